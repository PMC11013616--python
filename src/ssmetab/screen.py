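"""Four-criteria biomarker screening and univariate clinical statistics.

A metabolite is called a potential biomarker of a case/control contrast when
it jointly satisfies:

* covariate-adjusted p < 0.05 (linear regression of concentration on the
  group indicator with age and sex as covariates),
* |p(corr)| above the contrast's correlation threshold (0.300 by default,
  0.600 for the ADI-vs-ADC contrast),
* VIP in the top 10% — the 90th percentile of the per-bucket VIP distribution
  of the contrast's OPLS-DA model fitted to the Pareto-scaled bin matrix.
  A metabolite's VIP/p(corr) are read off its best assigned bucket.  (The
  latent model is fitted to buckets, as in bucket-based serum workflows; a
  metabolite-level reference population for the percentile is available via
  ``vip_reference="metabolites"``.)

Fold change is the ratio of case to control group means of the relative
concentrations.  The module also provides the univariate machinery used on
clinical tables: Pearson chi-square from counts, one-way ANOVA exactly
recoverable from per-group (n, mean, SD) summaries, Welch t and Mann-Whitney
tests, and the biomarker-clinical Pearson correlation network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chemometrics import LatentModel, fit_oplsda
from .exceptions import ConfigurationError, DomainError
from .spectra import BinMatrix, QuantTable, pareto_scale

#: default |p(corr)| threshold; the adolescent-ISS contrast uses a stricter one
DEFAULT_R_THRESHOLD = 0.300
ADI_ADC_R_THRESHOLD = 0.600


# ---------------------------------------------------------------------------
# univariate pieces
# ---------------------------------------------------------------------------

def fold_change(values: pd.DataFrame, case_mask, control_mask) -> pd.Series:
    """Per-metabolite ratio of case to control means; zero control mean -> NaN."""
    case_mask = np.asarray(case_mask, dtype=bool)
    control_mask = np.asarray(control_mask, dtype=bool)
    if case_mask.sum() == 0 or control_mask.sum() == 0:
        raise DomainError("both groups must be non-empty")
    case_mean = values.loc[case_mask].mean(axis=0)
    ctrl_mean = values.loc[control_mask].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = case_mean / ctrl_mean
    return fc.where(ctrl_mean != 0, np.nan)


def two_group_p(values: pd.DataFrame, case_mask, control_mask,
                method: str = "welch") -> pd.Series:
    """Raw two-group p per metabolite.

    ``method`` is one of ``welch`` (default), ``student`` (pooled-variance
    t, the classical clinical-table choice) or ``mannwhitney``.
    """
    case = values.loc[np.asarray(case_mask, dtype=bool)]
    ctrl = values.loc[np.asarray(control_mask, dtype=bool)]
    out = {}
    for met in values.columns:
        a, b = case[met].to_numpy(), ctrl[met].to_numpy()
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            out[met] = np.nan
            continue
        if method == "welch":
            out[met] = stats.ttest_ind(a, b, equal_var=False).pvalue
        elif method == "student":
            out[met] = stats.ttest_ind(a, b, equal_var=True).pvalue
        elif method == "mannwhitney":
            out[met] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        else:
            raise ConfigurationError(f"unknown test: {method}")
    return pd.Series(out)


def covariate_adjusted_p(
    values: pd.DataFrame,
    group_indicator,
    age,
    sex,
) -> pd.Series:
    """Group-coefficient p from ``concentration ~ group + age + sex`` OLS.

    Degenerate fits (constant metabolite, collinear design) yield NaN rather
    than raising; callers treat NaN as 'excluded and logged'.
    """
    g = np.asarray(group_indicator, dtype=float)
    columns = [np.ones_like(g), g]
    for cov in (np.asarray(age, dtype=float), np.asarray(sex, dtype=float)):
        if np.ptp(cov) > 0:  # constant covariates carry no information
            columns.append(cov)
    design = np.column_stack(columns)
    n, k = design.shape
    rank = np.linalg.matrix_rank(design)
    out = {}
    if rank < k or n <= k:
        return pd.Series({met: np.nan for met in values.columns})
    XtX_inv = np.linalg.inv(design.T @ design)
    H = XtX_inv @ design.T
    for met in values.columns:
        yv = values[met].to_numpy(dtype=float)
        if np.ptp(yv) == 0:
            out[met] = np.nan
            continue
        beta = H @ yv
        resid = yv - design @ beta
        sigma2 = float(resid @ resid) / (n - k)
        if sigma2 <= 0:
            out[met] = np.nan
            continue
        se = np.sqrt(sigma2 * XtX_inv[1, 1])
        t_stat = beta[1] / se
        out[met] = 2.0 * stats.t.sf(abs(t_stat), n - k)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# contrast screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenTable:
    """Per-metabolite statistics and the joint selection flag for one contrast."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # columns: FC, log2FC, p_raw, p_adj, cor, vip, selected
    r_threshold: float
    vip_cutoff: float
    model: LatentModel | None = None
    model_predictive: bool = True

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def volcano_frame(self) -> pd.DataFrame:
        cols = ["FC", "log2FC", "p_adj", "cor", "vip", "selected"]
        return self.table[cols].reset_index(names="metabolite")


def r_threshold_for(case: str, control: str) -> float:
    """The |p(corr)| threshold for a contrast (stricter for ADI vs ADC)."""
    if {case, control} == {"ADI", "ADC"}:
        return ADI_ADC_R_THRESHOLD
    return DEFAULT_R_THRESHOLD


def apply_selection(
    table: pd.DataFrame,
    r_threshold: float,
    vip_cutoff: float,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Attach the joint selection flag; rows missing any statistic never pass."""
    ok = (
        (table["p_adj"] < p_threshold)
        & (table["cor"].abs() > r_threshold)
        & (table["vip"] >= vip_cutoff)
    )
    out = table.copy()
    out["selected"] = ok.fillna(False).astype(bool)
    return out


def _metabolite_bins(bin_edges: np.ndarray,
                     assignment_map: dict[str, list[tuple[float, float]]]) -> dict[str, np.ndarray]:
    """Indices of the buckets overlapping each metabolite's assigned intervals."""
    lo, hi = bin_edges[:, 0], bin_edges[:, 1]
    out = {}
    for met, intervals in assignment_map.items():
        mask = np.zeros(len(bin_edges), dtype=bool)
        for a, b in intervals:
            mask |= (hi > a) & (lo < b)
        out[met] = np.flatnonzero(mask)
    return out


def screen_contrast(
    quant: QuantTable,
    bins: BinMatrix,
    clinical: pd.DataFrame,
    case: str,
    control: str,
    r_threshold: float | None = None,
    vip_percentile: float = 90.0,
    vip_reference: str = "bins",
    p_threshold: float = 0.05,
    n_orthogonal: int = 1,
    raw_test: str = "welch",
    cv_folds: int | None = 10,
    seed: int = 0,
    require_predictive: bool = True,
) -> ScreenTable:
    """Run the full four-criteria screen for one case/control contrast.

    Biomarkers are only ever read off a model with predictive power: when
    ``require_predictive`` is set (the default) and the contrast's OPLS-DA
    has cross-validated Q² <= 0, no metabolite is flagged — a model that
    cannot predict class membership is not interpreted, mirroring the
    validate-then-screen order of SIMCA-style workflows.  The per-metabolite
    statistics are still reported.
    """
    if r_threshold is None:
        r_threshold = r_threshold_for(case, control)
    groups = clinical["group"]
    mask = groups.isin([case, control]).to_numpy()
    sub_clin = clinical.loc[mask]
    sub_quant = quant.values.loc[mask]
    case_mask = (sub_clin["group"] == case).to_numpy()
    ctrl_mask = ~case_mask

    fc = fold_change(sub_quant, case_mask, ctrl_mask)
    p_raw = two_group_p(sub_quant, case_mask, ctrl_mask, method=raw_test)
    p_adj = covariate_adjusted_p(sub_quant, case_mask.astype(float),
                                 sub_clin["age"], sub_clin["sex"])

    if vip_reference not in {"bins", "metabolites"}:
        raise ConfigurationError(f"unknown vip_reference: {vip_reference}")
    if vip_reference == "bins":
        X = pareto_scale(bins.values[mask])
        model = fit_oplsda(X, case_mask.astype(int), n_orthogonal,
                           cv_folds=cv_folds, seed=seed)
        per_bin_vip, per_bin_cor = model.vip, model.pcorr
        vip_cutoff = float(np.percentile(per_bin_vip, vip_percentile))
        met_bins = _metabolite_bins(bins.bin_edges, quant.assignment_map)
        vip_vals, cor_vals = {}, {}
        for met in sub_quant.columns:
            idx = met_bins.get(met, np.array([], dtype=int))
            if idx.size == 0:
                vip_vals[met], cor_vals[met] = np.nan, np.nan
                continue
            best = idx[np.argmax(per_bin_vip[idx])]
            vip_vals[met] = float(per_bin_vip[best])
            cor_vals[met] = float(per_bin_cor[best])
        vip_ser, cor_ser = pd.Series(vip_vals), pd.Series(cor_vals)
    else:
        X = pareto_scale(sub_quant.to_numpy())
        model = fit_oplsda(X, case_mask.astype(int), n_orthogonal,
                           cv_folds=cv_folds, seed=seed)
        vip_ser = pd.Series(model.vip, index=sub_quant.columns)
        cor_ser = pd.Series(model.pcorr, index=sub_quant.columns)
        vip_cutoff = float(np.percentile(model.vip, vip_percentile))

    with np.errstate(divide="ignore"):
        table = pd.DataFrame({
            "FC": fc, "log2FC": np.log2(fc), "p_raw": p_raw, "p_adj": p_adj,
            "cor": cor_ser, "vip": vip_ser,
        })
    table = apply_selection(table, r_threshold, vip_cutoff, p_threshold)
    predictive = not (require_predictive and np.isfinite(model.q2) and model.q2 <= 0)
    if not predictive:
        table["selected"] = False
    return ScreenTable(contrast=(case, control), table=table,
                       r_threshold=r_threshold, vip_cutoff=vip_cutoff,
                       model=model, model_predictive=predictive)


# ---------------------------------------------------------------------------
# clinical table statistics
# ---------------------------------------------------------------------------

def chi_square_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise DomainError("counts must be non-negative")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected < 1):
        import warnings

        warnings.warn("expected cell count below 1; chi-square approximation is weak")
    return float(chi2), float(p)


def anova_from_summaries(groups: list[tuple[int, float, float]]) -> tuple[float, float]:
    """One-way ANOVA from per-group (n, mean, SD); exact via the SSB/SSW split.

    SDs are the sample standard deviations (ddof=1), as printed in clinical
    tables.  Identical group means give F = 0, p = 1.
    """
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    if np.any(sds < 0):
        raise DomainError("negative SD")
    if np.any(ns < 1) or len(groups) < 2:
        raise DomainError("need >= 2 groups with n >= 1")
    total_n = ns.sum()
    grand = float((ns * means).sum() / total_n)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    dfb, dfw = len(groups) - 1, int(total_n) - len(groups)
    if ssw == 0:
        return (np.inf, 0.0) if ssb > 0 else (0.0, 1.0)
    F = (ssb / dfb) / (ssw / dfw)
    return F, float(stats.f.sf(F, dfb, dfw))


def anova_from_raw(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA from raw per-group values (summary route on exact stats)."""
    summaries = [(len(g), float(np.mean(g)), float(np.std(g, ddof=1))) for g in groups]
    return anova_from_summaries(summaries)


def clinical_group_tests(
    clinical: pd.DataFrame,
    group_col: str = "group",
    categorical: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Chi-square for categorical and one-way ANOVA for continuous variables.

    Returns one row per clinical variable: (variable, test, statistic, p).
    """
    rows = []
    labels = clinical[group_col].unique()
    for col in clinical.columns:
        if col == group_col:
            continue
        if col in categorical:
            counts = pd.crosstab(clinical[col], clinical[group_col]).to_numpy()
            stat, p = chi_square_counts(counts)
            rows.append({"variable": col, "test": "chi-square", "statistic": stat, "p": p})
        else:
            per_group = [clinical.loc[clinical[group_col] == g, col].dropna().to_numpy()
                         for g in labels]
            stat, p = anova_from_raw(per_group)
            rows.append({"variable": col, "test": "anova", "statistic": stat, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation network
# ---------------------------------------------------------------------------

def correlation_network(
    biomarkers: pd.DataFrame,
    clinical: pd.DataFrame,
    p_threshold: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson r and two-sided p per (biomarker, clinical index) pair.

    Missing clinical values are pairwise-deleted; pairs with fewer than
    ``min_pairs`` complete observations are flagged missing.
    """
    rows = []
    for met in biomarkers.columns:
        x_all = biomarkers[met]
        for idx in clinical.columns:
            y_all = pd.to_numeric(clinical[idx], errors="coerce")
            ok = x_all.notna() & y_all.notna()
            n = int(ok.sum())
            if n < min_pairs:
                rows.append({"biomarker": met, "index": idx, "r": np.nan,
                             "p": np.nan, "n": n, "significant": False,
                             "missing": True})
                continue
            xv, yv = x_all[ok].to_numpy(), y_all[ok].to_numpy()
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(xv, yv)
            rows.append({"biomarker": met, "index": idx, "r": r, "p": p,
                         "n": n, "significant": bool(p < p_threshold) if p == p else False,
                         "missing": False})
    return pd.DataFrame(rows)
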