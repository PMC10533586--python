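# Methods

`pinetrace` analyses ¹³C-CO₂ pulse-chase experiments in tree–soil
mesocosms: a sapling crown is exposed to ¹³C-enriched CO₂ for ~45 minutes
and the label is then traced through needles, fine roots, soil pore CO₂
and microbial phospholipid fatty acids (PLFA) over a multi-week chase.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic test bed does and does not emulate.

## Isotope-excess accounting

Isotopic composition is measured as δ¹³C (‰ vs VPDB, ratio
r = 0.0111802) and converted to atom% ¹³C:

    atom% = 100 / ( 1 / ((δ/1000 + 1)·r) + 1 )

The tracer content of a compartment is its excess over the compartment's
own pre-label background:

    enrichment = (atom%_labelled − atom%_background) / 100
    excess     = enrichment · C_pool          [mg ¹³C m⁻²]
    release    = enrichment · CO₂-efflux      [mg ¹³C m⁻² h⁻¹]

Tissue C pools are biomass per ground area × %C; PLFA-C pools are
concentration (µg g⁻¹ dry soil) × areal soil dry mass (0–20 cm) × the
compound's carbon mass fraction. The background atom% is the mean over
the mesocosm × compartment's own pre-label samples (several samples are
averaged; there is no global default background). Between sampling dates
the pool measured nearest in time is used — no interpolation, since no
within-chase pool time-course rule is defensible from such sparse data.
Excess values may go slightly negative from measurement noise; they are
kept for fitting (truncating would bias the kinetics) and clipped at zero
only when reporting label fractions.

Conversion choices: δ = −1000 ‰ (zero ¹³C) is the domain boundary;
atom% = 100 is rejected in the inverse (infinite ratio). The round trip
is exact to ≤ 1e−10 ‰ across δ ∈ [−1000, 10⁵].

## Residence-time kinetics

Needle washout follows a single-pool first-order model
N(t) = N₀·e^(−λt), with mean residence time τ = 1/λ. The fit
(`ExponentialDecayModel`) is nonlinear least squares on the linear scale,
initialized from a log-linear regression of the positive excess values;
points before the observed series maximum are excluded, because N₀ is
defined at the labelling peak and earlier points belong to the uptake
transient. Fitting on the linear scale keeps legitimate near-zero and
slightly negative late-time observations in the fit, which log-scale
fitting would discard. A fitted λ ≤ 0 raises a flagged failure (no τ is
reported for a non-decaying series). Standard errors come from the
curve_fit covariance; τ's SE uses the delta method.

## Arrival lag and transport velocity

The arrival of label in soil pore CO₂ is the earliest *sampled* time
whose value exceeds background mean + k·SD (default k = 3) and remains
above at the next sample; no interpolated crossing is reported, because
the observable is grid-quantized by the gas-sampling schedule. The
whole-path transport velocity is tree height / arrival lag (cm d⁻¹).

Threshold estimation at the campaign level: pre-label gas samples are few
(three per treatment), so the background mean pools all pre-label gas
samples — the natural ¹³C abundance of soil CO₂ is a property of the
shared soil — and the single-sample SD is the median of the
within-treatment replicate SDs at each sampling time, over all treatments
and times, debiased for the replicate count (median of s/σ at the
group's degrees of freedom). The median makes the estimate insensitive to
times at which between-tree differences in the arrived signal dominate
the spread; on real data residual tree-to-tree variation only raises the
threshold, i.e. errs toward later detection. Detection runs per mesocosm;
the treatment lag is the median across its mesocosms (robust to a single
aberrant series), and each tree's velocity uses its own height with that
treatment lag, mirroring how such experiments report a single arrival
time per treatment.

## Fractions and cumulative release

Belowground allocation fractions divide a compartment's excess by the
needle excess measured 45 min after labelling (the maximum needle excess,
i.e. the total label assimilated) — not by the fitted N₀. Released label
is the trapezoidal integral of the release-rate series over a window
(day-to-hour conversion explicit). On the study's sparse gas schedule the
trapezoid rule overestimates the peaked release pulse by several percent;
quadrature error falls below 2 % only on schedules of ~0.25 d spacing.

## Soil CO₂ efflux model

The efflux entering the release calculation is modelled as a Q10
temperature response times a Michaelis-type moisture scalar:

    F(T, θ) = f_ref · q10^((T − t_ref)/10) · θ/(k_θ + θ)

with T soil temperature (°C), θ volumetric water content (%VWC),
f_ref the flux at t_ref under non-limiting moisture (mg C m⁻² h⁻¹),
t_ref = 20 °C fixed (fitting it would confound with f_ref). The form is
deliberately minimal — monotone in both drivers, saturating in moisture —
and sits behind a single `predict` interface so an alternative response
can be swapped in. Calibration is bounded nonlinear least squares;
designs with a single temperature or a single moisture level are refused
as degenerate rather than silently returning unidentifiable parameters.
Environment covariates are interpolated linearly in time; the model never
extrapolates beyond the monitoring record.

## PLFA analysis

Twenty fatty-acid biomarkers partition into general bacteria (14:0, 15:0,
16:0, 17:0, 18:0, 20:0), gram-positive (i15:0, a15:0, i16:0, i17:0,
a17:0), gram-negative (16:1ω7, 16:1ω5, cy17:0, 18:1ω7, cy19:0),
Actinobacteriota (10Me16:0, 10Me17:0, 10Me18:0) and fungi (18:2ω6,9).
Names are normalized ('w' → 'ω', leading 'C' stripped before digits,
case-insensitive); unknown compounds map to `unassigned` and are never
dropped silently. The fungal:bacterial ratio divides the fungal marker by
the summed bacterial markers; gram⁺:gram⁻ likewise. Per-compound carbon
mass fractions are parsed from nomenclature (chain length, double bonds,
cyclopropane ring, 10-methyl branch → CₙH₂ₙ₋₂d₋₂rO₂), with a per-compound
override for users with measured conversion factors. δ¹³C values are
taken as already derivatization-corrected.

Correspondence analysis operates on the treatment × compound
mean-relative-abundance matrix: SVD of the standardized chi-square
residual matrix D_r^(−1/2)(P − rcᵀ)D_c^(−1/2); principal coordinates are
the singular vectors scaled by margins and singular values; dimension
inertias are squared singular values and sum to χ²/n (asserted in tests
to 1e−10, and cross-checked against scikit-bio's implementation). An
independent (rank-zero residual) matrix is rejected as degenerate.

## Synthetic campaign generator

The generator emulates the study conditions: three treatments
(control / intermediate / severe water limitation) × three mesocosms,
tissue sampling at −1 d, 45 min, 1, 2, 3, 7, 14, 47 d, soil/PLFA sampling
at −1, 1, 2, 3, 7, 14, 47 d and gas sampling at −1 d, 1.5 h, 3 h, 1, 1.5,
2, 3, 5, 7, 14, 26, 47 d. Default treatment parameters are the study's
headline values: assimilated label 32.4 / 37.1 / 10.8 mg ¹³C m⁻², needle
τ 3.4 / 3.6 / 9.3 d, transport velocity 46 / 44 / 25 cm d⁻¹ with soil-CO₂
arrival at 1.5 / 1.5 / 3 d, release peaks at day 5 / 3 / 7, fungal PLFA
peak at day 2, moisture plateaus ~30 / 10 / 4 %VWC, pore CO₂
4079 / 1122 / 737 ppm, fungal:bacterial ratios 0.038 / 0.030 / 0.028,
needle biomass 35 / 34 / 25 g dw, tree heights per treatment chosen so
that mean(height)/arrival equals the stated velocity exactly
(66–72 / 63–69 / 72–78 cm; a single 72 cm height for all trees cannot
reconcile a 1.5 d sampled arrival with 46 cm d⁻¹).

Compartment kinetics: needle excess decays exponentially from the 45-min
sample; root excess rises after a 0.5 d lag as a saturating ramp toward
the transferred share (and is frozen thereafter — no root turnover within
the chase window, a modelling convention); the respired share arrives in
soil pore CO₂ as a shifted gamma kernel (shape 2) whose onset sits 0.4 d
before the nominal arrival day so the signal is already detectable at the
arrival sample, and whose mode is the release-peak day — a pure delay
could not reproduce arrival and peak independently; fungal PLFA excess is
a gamma-shaped pulse from day 1 peaking at day 2. Transfer fractions
(root 0.025–0.15, respired 0.20–0.42, fungal 0.001–0.004 of the
assimilated label) are not printed in the study; they were chosen once to
reproduce its observable consequences (a ~2 ‰ root δ shift at day 47,
detectable fungal δ shifts, a considerably lower released fraction under
severe limitation) and satisfy mass balance: needle + root + fungal +
cumulative respired + in-transit = assimilated at all times, with the
in-transit remainder non-negative (checked to 1e−9 at construction).

Measurement layer: true excess is converted to δ¹³C through the
compartment's C pool and Gaussian noise is added on the δ scale (IRMS
error is δ-additive): SD 0.3 ‰ needles, 0.5 ‰ roots, 1 ‰ gas, 2 ‰ PLFA.
PLFA concentrations carry 5 % multiplicative noise; pore CO₂ ppm carries
additive noise per treatment. The environment is hourly: a diurnal
temperature sinusoid (20 ± 5 °C) and treatment moisture plateaus, both
with small jitter. Identical seeds give bit-identical campaigns;
different seeds change only the noise, never the ground truth.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: between-tree variation in uptake and
kinetics within a treatment (only measurement noise separates replicate
trees), pool-size changes during the chase, diffusive smearing and
storage effects in soil gas transport, label recycling into structural
tissue, microbial turnover of the fungal marker after its peak, and any
treatment effect on the natural-abundance baselines.

## Problem sizes and runtimes

The default test suite simulates full campaigns (~1 500 measurement rows,
~10 800 hourly environment rows each) in tens of milliseconds; the
Monte-Carlo recovery check runs 200 seeded campaigns (~30 s) — sizes
chosen so the statistical claims (median τ error ≤ 5 %, grid-exact
velocity recovery) are tight at three mesocosms per treatment. The
acceptance script is a single campaign plus an efflux calibration on 261
flux observations and completes in ~2 s.

## Known limitations

- The efflux functional form is a stand-in interface: the study's own
  supplementary efflux equations were not specified in the main text, so
  a Q10 × Michaelis form was adopted; swap it behind `predict_efflux` if
  the original formulation is available.
- Residence time assumes a single well-mixed needle pool; multi-pool or
  lagged-export behaviour would bias τ̂ toward the slow pool.
- Velocity is a whole-path lag/height estimate quantized to the gas
  sampling grid, not a phloem-hydraulics quantity.
- Whether "total PLFA" should include the Actinobacteriota and fungal
  markers is ambiguous in the field; both `total_bacteria` and
  `total_all` are reported, labelled distinctly.
- Mixed-effects significance testing of treatment effects is out of
  scope; summaries are mean ± SE per treatment.
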