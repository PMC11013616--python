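"""Diagnostic model construction: LASSO feature selection, classifiers, ROC.

Candidates (metabolites with two-group p < 0.05) are filtered by
L1-penalised regression — the objective is ``1/2 ||y - Xb||^2 + lambda |b|_1``
with the penalty chosen by cross-validation and the one-standard-error rule —
and the surviving panel is handed to three classifiers (random forest,
logistic regression, RBF support-vector machine).  Performance is summarised
by ROC curves built from an explicit threshold sweep, AUC computed as the
normalised Mann-Whitney pairwise count (ties count 1/2), and a stratified
bootstrap percentile confidence interval.  Scores are cross-validated by
default; resubstitution is available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso, lasso_path
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import DomainError

# ---------------------------------------------------------------------------
# ROC / AUC primitives
# ---------------------------------------------------------------------------

def roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve by threshold sweep over the unique score values.

    Returns (FPR, TPR) as non-decreasing step coordinates from (0,0) to
    (1,1); tied scores are grouped so ties appear as diagonal segments.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise DomainError("need both classes for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order]
    # group tied scores
    distinct = np.concatenate([np.flatnonzero(np.diff(s)) + 1, [s.size]])
    tp = np.cumsum(l)[distinct - 1]
    fp = np.cumsum(~l)[distinct - 1]
    tpr = np.concatenate([[0.0], tp / l.sum()])
    fpr = np.concatenate([[0.0], fp / (~l).sum()])
    return fpr, tpr


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Area under a step ROC curve by the trapezoid rule."""
    return float(np.trapezoid(tpr, fpr))


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised count of correctly ordered case/control pairs.

    Equal scores count one half, so this equals the Mann-Whitney U statistic
    divided by ``n_pos * n_neg`` and, identically, the trapezoid area of the
    threshold-sweep ROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("need both classes")
    # rank-based computation: exact and O(n log n)
    allscores = np.concatenate([pos, neg])
    order = np.argsort(allscores, kind="mergesort")
    ranks = np.empty(allscores.size)
    ranks[order] = np.arange(1, allscores.size + 1)
    # average ranks over ties
    sorted_scores = allscores[order]
    i = 0
    while i < sorted_scores.size:
        j = i
        while j + 1 < sorted_scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = ranks[order[i : j + 1]].mean()
        i = j + 1
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(seed)
    pos_idx, neg_idx = np.flatnonzero(labels), np.flatnonzero(~labels)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        aucs[b] = auc_mann_whitney(scores[idx], labels[idx])
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# LASSO selection
# ---------------------------------------------------------------------------

@dataclass
class LassoResult:
    """Outcome of the penalised selection step."""

    selected: list[str]
    coefficients: pd.Series
    lambda_chosen: float
    lambda_max: float
    lambda_grid: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_se: np.ndarray


def lambda_max_value(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient: ``max_j |x_j'(y - ybar)|``."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)))


def lasso_coefficients(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients of ``1/2 ||y - b0 - Xb||^2 + lam * |b|_1`` at one penalty."""
    n = X.shape[0]
    if lam < 0:
        raise DomainError("penalty must be non-negative")
    model = Lasso(alpha=max(lam, 1e-12) / n, fit_intercept=True,
                  max_iter=200000, tol=1e-10)
    model.fit(X, y)
    return model.coef_


def lasso_select(
    X: pd.DataFrame,
    y,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    rule: str = "1se",
    standardize: bool = True,
) -> LassoResult:
    """Cross-validated LASSO over a log-spaced penalty grid.

    The penalty is chosen by the one-standard-error rule (largest penalty
    whose mean CV error is within one SE of the minimum) or ``rule="min"``.
    Selected features are the nonzero coefficients of the full-data fit at
    the chosen penalty.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{j}" for j in range(np.shape(X)[1])]
    Xm = np.asarray(X, dtype=float)
    y01 = np.asarray(y, dtype=float)
    if Xm.shape[1] < 1 or Xm.size == 0:
        raise DomainError("empty candidate set")
    if np.unique(y01).size < 2:
        raise DomainError("single-class response")
    if standardize:
        sd = Xm.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xm = (Xm - Xm.mean(axis=0)) / sd
    n = Xm.shape[0]
    lam_max = lambda_max_value(Xm, y01)
    if lambda_grid is None:
        lambda_grid = lam_max * np.logspace(0, -3, 100)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    alphas = lambda_grid / n

    k = min(cv_folds, int(np.min(np.bincount(y01.astype(int)))))
    k = max(k, 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_mse = np.empty((k, alphas.size))
    for f, (train, test) in enumerate(skf.split(Xm, y01.astype(int))):
        Xt, yt = Xm[train], y01[train]
        mu_x, mu_y = Xt.mean(axis=0), yt.mean()
        _, coefs, _ = lasso_path(Xt - mu_x, yt - mu_y, alphas=alphas, max_iter=100000)
        pred = (Xm[test] - mu_x) @ coefs + mu_y
        fold_mse[f] = np.mean((pred - y01[test, None]) ** 2, axis=0)
    mse_mean = fold_mse.mean(axis=0)
    mse_se = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)

    best = int(np.argmin(mse_mean))
    if rule == "1se":
        limit = mse_mean[best] + mse_se[best]
        admissible = np.flatnonzero(mse_mean <= limit)
        choice = int(admissible[0])  # grid is descending: first = largest penalty
    elif rule == "min":
        choice = best
    else:
        raise DomainError(f"unknown rule: {rule}")
    lam = float(lambda_grid[choice])
    coef = lasso_coefficients(Xm, y01, lam)
    series = pd.Series(coef, index=names)
    return LassoResult(
        selected=[nm for nm, c in series.items() if abs(c) > 1e-10],
        coefficients=series,
        lambda_chosen=lam,
        lambda_max=lam_max,
        lambda_grid=lambda_grid,
        cv_mse_mean=mse_mean,
        cv_mse_se=mse_se,
    )


# ---------------------------------------------------------------------------
# classifier evaluation
# ---------------------------------------------------------------------------

def _make_classifier(name: str, seed: int):
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "lr":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000, random_state=seed))
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=seed))
    raise DomainError(f"unknown classifier: {name}")


def _score(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        try:
            return clf.decision_function(X)
        except AttributeError:  # pragma: no cover
            pass
    return clf.predict_proba(X)[:, 1]


def cross_validated_scores(
    clf_name: str,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Held-out continuous scores from stratified k-fold cross-validation."""
    y = np.asarray(y).astype(int)
    min_class = int(np.min(np.bincount(y)))
    if min_class < k:
        warnings.warn(f"smallest class has {min_class} members; folds reduced")
        k = max(min_class, 2)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(y.size)
    for train, test in skf.split(X, y):
        clf = _make_classifier(clf_name, seed)
        clf.fit(X[train], y[train])
        scores[test] = _score(clf, X[test])
    return scores


@dataclass
class ClassifierReport:
    name: str
    auc: float
    ci_low: float
    ci_high: float
    fpr: np.ndarray
    tpr: np.ndarray


@dataclass
class DiagnosticReport:
    """Selected panel and per-classifier ROC summaries for one contrast."""

    contrast: tuple[str, str]
    candidates: list[str]
    lasso_selected: list[str]
    classifiers: dict[str, ClassifierReport]
    scheme: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "contrast": list(self.contrast),
            "candidates": self.candidates,
            "lasso_selected": self.lasso_selected,
            "scheme": self.scheme,
            "seed": self.seed,
            "classifiers": {
                nm: {
                    "auc": r.auc,
                    "ci": [r.ci_low, r.ci_high],
                    "roc": {"fpr": r.fpr.tolist(), "tpr": r.tpr.tolist()},
                }
                for nm, r in self.classifiers.items()
            },
        }


def fit_and_roc(
    X: pd.DataFrame,
    y,
    classifiers: tuple[str, ...] = ("rf", "lr", "svm"),
    scheme: str = "cv",
    k: int = 5,
    seed: int = 0,
    n_boot: int = 2000,
    contrast: tuple[str, str] = ("case", "control"),
    candidates: list[str] | None = None,
    lasso_selected: list[str] | None = None,
) -> DiagnosticReport:
    """Evaluate classifiers on a selected feature panel.

    ``scheme="cv"`` scores every sample from the fold that held it out;
    ``scheme="resubstitution"`` scores the training data itself (optimistic,
    kept for comparison with software that reports apparent performance).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xm = np.asarray(X, dtype=float)
    if Xm.shape[1] == 0:
        raise DomainError("selected feature set is empty")
    y01 = np.asarray(y).astype(int)
    reports = {}
    for i, name in enumerate(classifiers):
        clf_seed = seed + 1000 * i
        if scheme == "cv":
            scores = cross_validated_scores(name, Xm, y01, k=k, seed=clf_seed)
        elif scheme == "resubstitution":
            clf = _make_classifier(name, clf_seed)
            clf.fit(Xm, y01)
            scores = _score(clf, Xm)
        else:
            raise DomainError(f"unknown scheme: {scheme}")
        fpr, tpr = roc_points(scores, y01)
        auc = auc_mann_whitney(scores, y01)
        lo, hi = bootstrap_auc_ci(scores, y01, n_boot=n_boot, seed=clf_seed)
        reports[name] = ClassifierReport(name=name, auc=auc, ci_low=lo,
                                         ci_high=hi, fpr=fpr, tpr=tpr)
    return DiagnosticReport(
        contrast=contrast,
        candidates=candidates if candidates is not None else (names or []),
        lasso_selected=lasso_selected if lasso_selected is not None else (names or []),
        classifiers=reports,
        scheme=scheme,
        seed=seed,
    )


def diagnose_contrast(
    quant_values: pd.DataFrame,
    clinical: pd.DataFrame,
    case: str,
    control: str,
    p_threshold: float = 0.05,
    classifiers: tuple[str, ...] = ("rf", "lr", "svm"),
    scheme: str = "cv",
    k: int = 5,
    seed: int = 0,
    n_boot: int = 2000,
    raw_test: str = "welch",
) -> DiagnosticReport:
    """Full diagnostic-model construction for one contrast.

    Candidates are metabolites with raw two-group p < ``p_threshold``; the
    LASSO panel then feeds the classifiers.  When the one-SE penalty zeroes
    everything, the candidate set itself is used (noted in the report by
    ``lasso_selected == candidates``).
    """
    from .screen import two_group_p  # local import to avoid a cycle

    mask = clinical["group"].isin([case, control]).to_numpy()
    sub = quant_values.loc[mask]
    y01 = (clinical.loc[mask, "group"] == case).to_numpy().astype(int)
    p_raw = two_group_p(sub, y01 == 1, y01 == 0, method=raw_test)
    candidates = [m for m in sub.columns if p_raw[m] < p_threshold]
    if len(candidates) < 2:
        raise DomainError(
            f"{case} vs {control}: need >= 2 candidate metabolites, got {len(candidates)}"
        )
    sel = lasso_select(sub[candidates], y01, seed=seed)
    panel = sel.selected if sel.selected else candidates
    return fit_and_roc(
        sub[panel], y01, classifiers=classifiers, scheme=scheme, k=k,
        seed=seed, n_boot=n_boot, contrast=(case, control),
        candidates=candidates, lasso_selected=panel,
    )
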