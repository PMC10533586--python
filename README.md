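# pinetrace

Analysis toolkit for **¹³C-CO₂ pulse-chase experiments in tree–soil
mesocosms**: trace freshly assimilated carbon from a sapling's crown into
needles, fine roots, soil pore CO₂ and the phospholipid fatty acids
(PLFA) of soil microbial groups, and quantify how water limitation shifts
those allocation dynamics.

It is written for ecophysiologists and biogeochemists running pulse
labelling campaigns: the package turns long-format δ¹³C time series into
isotope excess, residence times, transport velocities, microbial uptake
and label fractions, and ships a compartmental simulator with exact
ground truth so every estimator is testable without field data.

## The model

Isotopic composition δ¹³C (‰ vs VPDB, r = 0.0111802) converts to atom%,

    atom% = 100 / (1/((δ/1000 + 1)·r) + 1),

and a compartment's tracer content is its **¹³C excess** over its own
pre-label background:

    ¹³C excess = (atom%ₗ − atom%ₙ)/100 · C pool        [mg ¹³C m⁻²]
    ¹³C release = (atom%ₗ − atom%ₙ)/100 · CO₂ efflux   [mg ¹³C m⁻² h⁻¹]

On top of that accounting:

- **Mean residence time** — needle washout N(t) = N₀e^(−λt), τ = 1/λ,
  fitted from the labelling peak onward (`ExponentialDecayModel`).
- **Transport velocity** — tree height / arrival lag of the ¹³C signal in
  soil pore CO₂ (threshold: background + 3 SD, sustained).
- **Soil CO₂ efflux** — F = f_ref·q10^((T−20)/10)·θ/(k_θ+θ), calibrated
  to flux observations (`EffluxModel`).
- **PLFA** — 20 biomarkers classified into general bacteria, gram⁺,
  gram⁻, Actinobacteriota and fungi; group totals, fungal:bacterial and
  gram⁺:gram⁻ ratios, per-compound ¹³C excess, correspondence analysis.
- **Fractions** — compartment excess normalized by the needle excess at
  45 min (the total label assimilated).

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from pinetrace import ExponentialDecayModel, build_excess_series
from pinetrace.simulate import default_scenario, simulate_campaign
from pinetrace import pipeline

table, truth = simulate_campaign(default_scenario(seed=42))

series = build_excess_series(table, "needle", "S1")   # severe-treatment tree
print(ExponentialDecayModel(series).fit().summary())

vel = pipeline.transport_summary(table)
print(vel.groupby("treatment")[["arrival_lag_d", "velocity_cm_d"]].mean())
```

```
First-order washout fit  N(t) = N0 exp(-lambda t)
  n points (from peak): 7
  N0     =    10.8192 +/- 0.1055  mg 13C m-2
  lambda =     0.1087 +/- 0.0033  day-1
  tau    =     9.1988 +/- 0.2794  days
  RSS    = 0.111489

              arrival_lag_d  velocity_cm_d
treatment
control                 1.5           46.0
intermediate            1.5           44.0
severe                  3.0           25.0
```

The severely water-limited tree retains its label far longer
(τ ≈ 9.2 d vs ~3.4 d for well-watered controls) and moves carbon to the
rhizosphere at roughly half the velocity — slower carbon cycling under
drought, with the label arriving in soil CO₂ only after 3 days.

The same chain is available from the shell:

```sh
pinetrace simulate --seed 42 --out campaign.csv --truth truth.json
pinetrace kinetics --in campaign.csv --what mrt --out mrt.csv
pinetrace plfa --in campaign.csv --out plfa_summary.csv
pinetrace report --in campaign.csv --out report.csv
```

Campaigns are long CSVs with one observation per row and columns
`mesocosm_id, treatment, compartment, time_d, delta13c_permil, co2_ppm,
carbon_pct, biomass_g_m2, plfa_ug_gdw` (times in days since the end of
the 45-min labelling window, negative = pre-label baseline; missing
values are empty cells, never zeros). Mesocosm metadata and the
continuous temperature/moisture record travel in
`<stem>.mesocosms.csv` / `<stem>.environment.csv` sidecars;
`pinetrace.data.import_xlsx` adapts spreadsheet layouts onto this
contract.

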