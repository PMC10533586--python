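"""PLFA biomarker classification, group aggregation, pools, excess, CA."""

import numpy as np
import pandas as pd
import pytest

from pinetrace.plfa import (BIOMARKER_GROUPS, CAResult, carbon_fraction,
                            classify_plfa, correspondence_analysis,
                            group_summary, normalize_name, plfa_c_pool,
                            plfa_excess, relative_abundance_matrix)


@pytest.mark.parametrize("name, group", [
    ("18:2ω6,9", "fungi"),
    ("18:2w6,9", "fungi"),            # 'w' spelling
    ("10Me17:0", "actinobacteriota"),
    ("16:1ω5", "gram_negative"),
    ("C16:0", "general_bacteria"),    # leading 'C' for saturated acids
    ("16:0", "general_bacteria"),
    ("i15:0", "gram_positive"),
    ("A17:0", "gram_positive"),       # case-insensitive
    ("19:0", "unassigned"),
])
def test_biomarker_classification(name, group):
    assert classify_plfa(name) == group


def test_partition_counts_of_the_twenty_biomarkers():
    """6 general / 5 gram+ / 5 gram- / 3 Actinobacteriota / 1 fungal."""
    sizes = {g: len(n) for g, n in BIOMARKER_GROUPS.items()}
    assert sizes == {"general_bacteria": 6, "gram_positive": 5,
                     "gram_negative": 5, "actinobacteriota": 3, "fungi": 1}
    all_names = [n for names in BIOMARKER_GROUPS.values() for n in names]
    assert len(all_names) == 20
    assert all(classify_plfa(n) != "unassigned" for n in all_names)


def test_normalization_idempotent():
    assert normalize_name("C16:0") == normalize_name("16:0") == "16:0"
    assert normalize_name(normalize_name("18:2W6,9")) == "18:2ω6,9"


class TestGroupSummary:
    def test_fb_ratio_toy(self):
        prof = pd.DataFrame({"compound": ["18:2ω6,9", "C16:0"],
                             "conc_ug_gdw": [1.0, 10.0]})
        gs = group_summary(prof)
        assert gs.fb_ratio == pytest.approx(0.1)
        assert gs.total_bacteria == pytest.approx(10.0)

    def test_gp_gn_ratio_of_equal_sums_is_one(self):
        prof = pd.DataFrame({
            "compound": ["i15:0", "a15:0", "16:1ω7", "cy19:0"],
            "conc_ug_gdw": [2.0, 3.0, 1.0, 4.0]})
        assert group_summary(prof).gp_gn_ratio == pytest.approx(1.0)

    def test_zero_bacteria_flags_undefined_ratio(self):
        prof = pd.DataFrame({"compound": ["18:2ω6,9"], "conc_ug_gdw": [1.0]})
        with pytest.warns(UserWarning, match="undefined"):
            gs = group_summary(prof)
        assert np.isnan(gs.fb_ratio)

    def test_fb_ratio_scale_invariant(self):
        prof = pd.DataFrame({"compound": ["18:2ω6,9", "16:0", "i15:0"],
                             "conc_ug_gdw": [0.5, 8.0, 2.0]})
        a = group_summary(prof).fb_ratio
        prof2 = prof.assign(conc_ug_gdw=prof["conc_ug_gdw"] * 13.7)
        assert group_summary(prof2).fb_ratio == pytest.approx(a, rel=1e-12)

    def test_totals_additive_and_bacteria_sum(self):
        prof = pd.DataFrame({
            "compound": ["16:0", "i15:0", "cy19:0", "10Me16:0", "18:2ω6,9"],
            "conc_ug_gdw": [4.0, 2.0, 1.0, 0.5, 0.3]})
        gs = group_summary(prof)
        assert gs.total_bacteria == pytest.approx(
            gs.totals["general_bacteria"] + gs.totals["gram_positive"]
            + gs.totals["gram_negative"])
        assert gs.total_all == pytest.approx(7.8)

    def test_simulator_community_ratio_recovered_noiselessly(
            self, noiseless_campaign):
        """The configured control fungal:bacterial ratio (0.038) comes back
        exactly when concentrations carry no noise."""
        from pinetrace.plfa import plfa_profiles
        _, table, _ = noiseless_campaign
        prof = plfa_profiles(table)
        one = prof[(prof["mesocosm_id"] == "C1") & (prof["time_d"] == 1.0)]
        assert group_summary(one[["compound", "conc_ug_gdw"]]).fb_ratio == \
            pytest.approx(0.038, abs=1e-12)


@pytest.mark.parametrize("name, formula_cfrac", [
    # molecular formulas: C16H32O2, C18H32O2, C19H36O2, C17H34O2 (10Me16:0)
    ("16:0", 16 * 12.011 / (16 * 12.011 + 32 * 1.008 + 2 * 15.999)),
    ("18:2ω6,9", 18 * 12.011 / (18 * 12.011 + 32 * 1.008 + 2 * 15.999)),
    ("cy19:0", 19 * 12.011 / (19 * 12.011 + 36 * 1.008 + 2 * 15.999)),
    ("10Me16:0", 17 * 12.011 / (17 * 12.011 + 34 * 1.008 + 2 * 15.999)),
])
def test_carbon_fraction_from_nomenclature(name, formula_cfrac):
    assert carbon_fraction(name) == pytest.approx(formula_cfrac, abs=1e-12)


def test_plfa_c_pool_arithmetic():
    assert plfa_c_pool(1.0, 200.0, carbon_frac=0.75) == pytest.approx(150.0)
    assert plfa_c_pool(0.0, 200.0, carbon_frac=0.75) == 0.0
    with pytest.raises(ValueError):
        plfa_c_pool(1.0, 200.0)


class TestPlfaExcess:
    def test_baseline_equals_labelled_gives_zero(self, noiseless_campaign):
        _, table, _ = noiseless_campaign
        per_compound, _ = plfa_excess(table, "C1")
        bacterial = per_compound["16:0"]
        assert np.allclose(bacterial.values, 0.0, atol=1e-9)

    def test_fungal_group_excess_matches_ground_truth(self, noiseless_campaign):
        """Chain conc -> pool -> excess reproduces the injected fungal label."""
        _, table, truth = noiseless_campaign
        _, groups = plfa_excess(table, "S1")
        fungi = groups["fungi"]
        expected = truth.fungal_excess("severe", fungi.times)
        np.testing.assert_allclose(fungi.values, expected, atol=1e-9)

    def test_group_fungi_is_single_marker(self, noiseless_campaign):
        _, table, _ = noiseless_campaign
        per_compound, groups = plfa_excess(table, "C1")
        np.testing.assert_allclose(groups["fungi"].values,
                                   per_compound["18:2ω6,9"].values)

    def test_fungal_peak_at_day_two(self, noiseless_campaign):
        from pinetrace.kinetics import peak_time
        _, table, _ = noiseless_campaign
        _, groups = plfa_excess(table, "S2")
        assert peak_time(groups["fungi"].after(0.0)) == pytest.approx(2.0)


class TestCorrespondenceAnalysis:
    def test_independent_matrix_has_zero_inertia(self):
        rows = np.array([0.3, 0.7])
        cols = np.array([0.2, 0.5, 0.3])
        m = pd.DataFrame(np.outer(rows, cols) * 100)
        with pytest.raises(ValueError, match="independent|degenerate"):
            correspondence_analysis(m)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.uniform(0.1, 5.0, (3, 15)),
                         index=["control", "intermediate", "severe"])
        res = correspondence_analysis(m)
        perm = ["severe", "control", "intermediate"]
        res_p = correspondence_analysis(m.loc[perm])
        got = res_p.row_coords.loc[res.row_coords.index]
        # coordinates agree up to a global sign per dimension
        for dim in res.row_coords.columns:
            a, b = res.row_coords[dim], got[dim]
            assert np.allclose(a, b, atol=1e-10) or \
                np.allclose(a, -b, atol=1e-10)

    def test_inertia_equals_chi_square_over_n(self):
        from scipy.stats import chi2_contingency
        rng = np.random.default_rng(9)
        for _ in range(5):
            m = rng.uniform(0.5, 10.0, (4, 7))
            res = correspondence_analysis(pd.DataFrame(m))
            chi2 = chi2_contingency(m, correction=False)[0]
            assert res.total_inertia == pytest.approx(chi2 / m.sum(),
                                                      abs=1e-10)
            assert np.all(np.diff(res.inertia) <= 1e-12)

    def test_reconstitution_of_correspondence_matrix(self):
        """Principal coordinates expand back to P via the reconstitution
        formula P_ij = r_i c_j (1 + sum_k f_ik g_jk / sigma_k)."""
        rng = np.random.default_rng(5)
        m = rng.uniform(0.1, 5.0, (3, 15))
        res = correspondence_analysis(pd.DataFrame(m))
        P = m / m.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        sv = np.sqrt(res.inertia)
        F, G = res.row_coords.to_numpy(), res.col_coords.to_numpy()
        recon = np.outer(r, c) * (1.0 + (F / sv) @ G.T)
        np.testing.assert_allclose(recon, P, atol=1e-10)

    def test_weighted_centroids_at_origin(self):
        rng = np.random.default_rng(11)
        m = rng.uniform(0.1, 5.0, (3, 8))
        res = correspondence_analysis(pd.DataFrame(m))
        P = m / m.sum()
        r, c = P.sum(axis=1), P.sum(axis=0)
        assert np.allclose(r @ res.row_coords.to_numpy(), 0.0, atol=1e-10)
        assert np.allclose(c @ res.col_coords.to_numpy(), 0.0, atol=1e-10)

    def test_agrees_with_reference_implementation(self):
        """Cross-check inertia and coordinates against scikit-bio's CA."""
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(21)
        m = pd.DataFrame(rng.uniform(0.5, 10.0, (4, 6)),
                         index=list("abcd"), columns=list("uvwxyz"))
        mine = correspondence_analysis(m)
        ref = skbio_ord.ca(m, scaling=1)
        np.testing.assert_allclose(
            np.sort(mine.inertia)[::-1],
            np.sort(ref.proportion_explained * mine.total_inertia)[::-1],
            atol=1e-8)

    def test_negative_or_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[1.0, -0.1], [0.2, 0.3]]))
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[0.0, 0.0], [0.2, 0.3]]))


def test_relative_abundance_matrix_shape(default_campaign):
    _, table, _ = default_campaign
    m = relative_abundance_matrix(table)
    assert m.shape == (3, 20)
    np.testing.assert_allclose(m.sum(axis=1), 1.0, rtol=1e-12)
    res = correspondence_analysis(m)
    assert isinstance(res, CAResult)
    assert res.total_inertia > 0
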