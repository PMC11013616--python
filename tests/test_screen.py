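"""Biomarker screening, covariate correction and clinical-table statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ssmetab as sm
from ssmetab.exceptions import DomainError
from ssmetab.screen import apply_selection


def _quant_frame(rng, n=80, p=20, prefix="m"):
    return pd.DataFrame(rng.lognormal(0.0, 0.2, size=(n, p)),
                        columns=[f"{prefix}{j}" for j in range(p)])


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def test_fold_change_identical_groups_is_one():
    rng = np.random.default_rng(0)
    vals = _quant_frame(rng, n=40)
    half = np.arange(40) < 20
    vals.iloc[half.nonzero()[0]] = vals.iloc[(~half).nonzero()[0]].to_numpy()
    fc = sm.fold_change(vals, half, ~half)
    assert np.allclose(fc, 1.0)


def test_fold_change_reciprocity():
    rng = np.random.default_rng(1)
    vals = _quant_frame(rng)
    case = np.arange(80) < 30
    fwd = sm.fold_change(vals, case, ~case)
    rev = sm.fold_change(vals, ~case, case)
    assert np.allclose(fwd * rev, 1.0)


def test_fold_change_matches_planted_effect_at_large_n():
    design = sm.CohortDesign(seed=2, groups=(("PAC", 400), ("PAG", 400)),
                             effects={"PAG": {"choline": 1.5}}, planted={})
    conc, clinical, _ = sm.generate_cohort(design)
    case = (clinical["group"] == "PAG").to_numpy()
    fc = sm.fold_change(conc, case, ~case)
    assert fc["choline"] == pytest.approx(1.5, rel=0.05)


# ---------------------------------------------------------------------------
# covariate-adjusted p
# ---------------------------------------------------------------------------

def test_adjusted_p_tracks_raw_p_when_covariates_are_irrelevant():
    """With covariates independent of group and metabolite the adjusted p
    ranks like the raw p (chance covariate correlations vanish as n grows)."""
    rhos = []
    for seed in range(5):
        rng = np.random.default_rng(3 + seed)
        n = 300
        vals = _quant_frame(rng, n=n, p=50)
        group = (np.arange(n) < n // 2).astype(float)
        age = rng.uniform(4, 14, n)
        sex = rng.integers(0, 2, n)
        p_adj = sm.covariate_adjusted_p(vals, group, age, sex)
        # pooled-variance test: the OLS group term's own family
        p_raw = sm.two_group_p(vals, group == 1, group == 0, method="student")
        rhos.append(stats.spearmanr(p_adj, p_raw).statistic)
    assert np.mean(rhos) > 0.95


def test_age_confounded_signal_removed_by_adjustment():
    """A metabolite driven purely by age loses significance after correction
    when the groups differ in age."""
    removed = 0
    for seed in range(20):
        rng = np.random.default_rng(400 + seed)
        n = 120
        group = (np.arange(n) < n // 2).astype(float)
        age = rng.normal(7.0 + 2.0 * group, 1.5)
        conc = np.exp(0.10 * age + rng.normal(0, 0.15, n))
        vals = pd.DataFrame({"met": conc})
        p_raw = sm.two_group_p(vals, group == 1, group == 0)["met"]
        p_adj = sm.covariate_adjusted_p(vals, group, age, np.zeros(n))["met"]
        if p_raw < 0.05 and p_adj > 0.05:
            removed += 1
    assert removed >= 16  # >= 80% of seeded repeats


def test_constant_metabolite_flagged_missing():
    vals = pd.DataFrame({"flat": np.ones(30)})
    group = (np.arange(30) < 15).astype(float)
    p = sm.covariate_adjusted_p(vals, group, np.arange(30.0), np.zeros(30))
    assert np.isnan(p["flat"])


def test_collinear_design_flagged_missing():
    group = (np.arange(30) < 15).astype(float)
    vals = pd.DataFrame({"m": np.random.default_rng(5).normal(size=30)})
    p = sm.covariate_adjusted_p(vals, group, np.arange(30.0), group)  # sex == group
    assert np.isnan(p["m"])


# ---------------------------------------------------------------------------
# joint selection rule
# ---------------------------------------------------------------------------

def _stats_table():
    rng = np.random.default_rng(6)
    vips = np.sort(rng.uniform(0.2, 2.0, 100))
    table = pd.DataFrame({
        "p_adj": np.full(100, 0.5), "cor": np.zeros(100), "vip": vips,
        "FC": np.ones(100),
    }, index=[f"m{j}" for j in range(100)])
    # one metabolite exactly at the interesting boundary: p=0.04, |cor|=0.31,
    # VIP at the 91st percentile
    table.loc["m91", ["p_adj", "cor"]] = [0.04, 0.31]
    return table


def test_boundary_metabolite_selected_at_default_threshold():
    table = _stats_table()
    cutoff = float(np.percentile(table["vip"], 90))
    out = apply_selection(table, r_threshold=0.300, vip_cutoff=cutoff)
    assert bool(out.loc["m91", "selected"])


def test_boundary_metabolite_rejected_at_stricter_adolescent_threshold():
    table = _stats_table()
    cutoff = float(np.percentile(table["vip"], 90))
    out = apply_selection(table, r_threshold=0.600, vip_cutoff=cutoff)
    assert not bool(out.loc["m91", "selected"])
    assert sm.screen.r_threshold_for("ADI", "ADC") == 0.600
    assert sm.screen.r_threshold_for("PAG", "PAC") == 0.300


def test_selection_monotone_in_every_threshold():
    rng = np.random.default_rng(7)
    table = pd.DataFrame({
        "p_adj": rng.uniform(0, 1, 200),
        "cor": rng.uniform(-1, 1, 200),
        "vip": rng.uniform(0, 3, 200),
    })
    base = apply_selection(table, 0.3, 1.0, 0.05)["selected"]
    for r, v, p in [(0.4, 1.0, 0.05), (0.3, 1.5, 0.05), (0.3, 1.0, 0.01),
                    (0.6, 2.0, 0.01)]:
        tight = apply_selection(table, r, v, p)["selected"]
        assert not np.any(tight & ~base)


def test_missing_statistics_never_select():
    table = pd.DataFrame({
        "p_adj": [0.01, np.nan], "cor": [np.nan, 0.9], "vip": [2.0, 2.0],
    }, index=["a", "b"])
    out = apply_selection(table, 0.3, 1.0)
    assert not out["selected"].any()


# ---------------------------------------------------------------------------
# clinical statistics
# ---------------------------------------------------------------------------

def test_chi_square_without_continuity_correction():
    # 2x3 sex-by-group table against the hand-computed Pearson formula
    table = np.array([[20, 30], [25, 25], [15, 35]]).T
    chi2, p = sm.chi_square_counts(table)
    expected_cells = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    pearson = float(((table - expected_cells) ** 2 / expected_cells).sum())
    assert chi2 == pytest.approx(pearson, rel=1e-12)
    assert p == pytest.approx(stats.chi2.sf(pearson, 2), rel=1e-12)


def test_anova_from_summaries_equals_anova_from_raw():
    rng = np.random.default_rng(8)
    groups = [rng.normal(10 + d, 2.0, size=n) for d, n in [(0, 25), (0.8, 30), (0.3, 20)]]
    f_sum, p_sum = sm.anova_from_raw(groups)
    f_ref, p_ref = stats.f_oneway(*groups)
    assert f_sum == pytest.approx(f_ref, rel=1e-10)
    assert p_sum == pytest.approx(p_ref, rel=1e-10)


def test_anova_identical_groups_f_zero_p_one():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    f, p = sm.anova_from_raw([g, g.copy(), g.copy()])
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_anova_negative_sd_rejected():
    with pytest.raises(DomainError):
        sm.anova_from_summaries([(10, 1.0, -0.5), (10, 2.0, 0.5)])


def test_clinical_group_tests_dispatch_by_variable_kind():
    rng = np.random.default_rng(9)
    clin = pd.DataFrame({
        "group": np.repeat(["A", "B", "C"], 30),
        "sex": rng.integers(0, 2, 90),
        "age": rng.normal(8, 2, 90),
    })
    report = sm.clinical_group_tests(clin)
    tests = dict(zip(report["variable"], report["test"]))
    assert tests == {"sex": "chi-square", "age": "anova"}
    assert ((report["p"] >= 0) & (report["p"] <= 1)).all()


# ---------------------------------------------------------------------------
# correlation network
# ---------------------------------------------------------------------------

def test_network_self_correlation_is_one():
    rng = np.random.default_rng(10)
    x = pd.DataFrame({"m": rng.normal(size=50)})
    net = sm.correlation_network(x, x.rename(columns={"m": "m_again"}))
    assert net.loc[0, "r"] == pytest.approx(1.0)


def test_network_exact_linear_relation():
    x = pd.DataFrame({"m": np.arange(1.0, 31.0)})
    clin = pd.DataFrame({"idx": 2.0 * np.arange(1.0, 31.0)})
    net = sm.correlation_network(x, clin)
    assert net.loc[0, "r"] == pytest.approx(1.0)
    assert net.loc[0, "p"] < 1e-10
    assert bool(net.loc[0, "significant"])


def test_network_null_relation_close_to_nominal_false_positive_rate():
    rng = np.random.default_rng(11)
    x = pd.DataFrame(rng.normal(size=(60, 50)), columns=[f"m{j}" for j in range(50)])
    clin = pd.DataFrame({"idx": rng.normal(size=60)})
    net = sm.correlation_network(x, clin)
    assert net["r"].abs().mean() < 0.2
    assert net["significant"].mean() <= 0.15  # ~5% nominal, wide band


def test_network_too_few_pairs_flagged_missing():
    x = pd.DataFrame({"m": [1.0, 2.0, np.nan, np.nan, np.nan]})
    clin = pd.DataFrame({"idx": [1.0, np.nan, 2.0, 3.0, 4.0]})
    net = sm.correlation_network(x, clin)
    assert bool(net.loc[0, "missing"])
    assert np.isnan(net.loc[0, "r"])


# ---------------------------------------------------------------------------
# end-to-end screen behaviour
# ---------------------------------------------------------------------------

def test_screen_recovers_planted_preadolescent_biomarkers(pag_pac_screen):
    table, manifest = pag_pac_screen
    planted = manifest.planted[("PAG", "PAC")]
    selected = set(table.selected)
    recall = len(selected & planted) / len(planted)
    assert recall >= 0.8
    assert len(selected - planted) <= 2
    assert table.model_predictive


def test_screen_fold_change_directions_match_plan(pag_pac_screen):
    table, manifest = pag_pac_screen
    fc = table.table["FC"]
    assert fc["vldl"] < 1 and fc["lipid"] < 1 and fc["lactate"] < 1
    assert fc["glycerol"] > 1 and fc["succinate"] > 1 and fc["phosphocholine"] > 1
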