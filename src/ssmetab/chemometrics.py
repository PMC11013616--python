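"""Latent-variable modelling for two-class metabolomics discrimination.

Implements the SIMCA-style toolchain from first principles:

* PCA by singular value decomposition,
* two-class PLS-DA by NIPALS (single response, so each component is exact),
* OPLS-DA by the orthogonal-signal-correction embedding of Trygg & Wold,
  separating class-predictive from class-orthogonal variation,
* VIP (variable importance in projection) whose squares average to 1,
* p(corr): the Pearson correlation of each variable with the predictive score,
* stratified k-fold cross-validated Q² with an Eriksson-style CV-ANOVA F-test,
* label-permutation validation with R²/Q² intercepts at zero label
  correlation.

All fits centre X and y internally, so the caller passes the (Pareto-)scaled
matrix and an unmodified class indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import DomainError

_EPS = 1e-12


def _encode_two_class(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DomainError(f"need exactly two classes, got {classes.size}")
    return (y == classes[1]).astype(float)


@dataclass
class LatentModel:
    """A fitted PCA / PLS-DA / OPLS-DA model."""

    kind: str
    weights: np.ndarray          # (p, A) predictive x-weights
    loadings: np.ndarray         # (p, A) predictive x-loadings
    scores: np.ndarray           # (n, A) predictive scores
    y_loadings: np.ndarray       # (A,)
    x_mean: np.ndarray
    y_mean: float
    r2x: float
    r2x_per_component: np.ndarray
    r2y: float = np.nan
    ortho_weights: np.ndarray | None = None
    ortho_loadings: np.ndarray | None = None
    ortho_scores: np.ndarray | None = None
    q2: float = np.nan
    cv_anova_p: float = np.nan
    vip: np.ndarray | None = None
    pcorr: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_orthogonal(self) -> int:
        return 0 if self.ortho_weights is None else self.ortho_weights.shape[1]

    # -- prediction -------------------------------------------------------
    def _remove_orthogonal(self, Xc: np.ndarray) -> np.ndarray:
        if self.ortho_weights is None:
            return Xc
        Xc = Xc.copy()
        for a in range(self.ortho_weights.shape[1]):
            t_o = Xc @ self.ortho_weights[:, a]
            Xc -= np.outer(t_o, self.ortho_loadings[:, a])
        return Xc

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores for new observations."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        if self.kind == "PCA":
            return Xc @ self.loadings
        Xc = self._remove_orthogonal(Xc)
        if self.kind == "OPLSDA":
            return Xc @ self.weights
        # PLS scores require the (P'W)^-1 rotation when A > 1
        rot = self.weights @ np.linalg.inv(self.loadings.T @ self.weights)
        return Xc @ rot

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction (regression on the indicator)."""
        if self.kind == "PCA":
            raise DomainError("PCA has no class prediction")
        return self.transform(X) @ self.y_loadings + self.y_mean


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: np.ndarray, n_components: int = 2) -> LatentModel:
    """Successive maximal-variance orthogonal components via SVD."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise DomainError("empty matrix")
    if n_components < 1 or n_components > min(X.shape):
        raise DomainError("n_components must be in [1, min(n, p)]")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ssx = float(np.sum(Xc**2))
    A = n_components
    scores = U[:, :A] * s[:A]
    loadings = Vt[:A].T
    r2x_comp = s[:A] ** 2 / ssx if ssx > 0 else np.zeros(A)
    return LatentModel(
        kind="PCA",
        weights=loadings.copy(),
        loadings=loadings,
        scores=scores,
        y_loadings=np.zeros(A),
        x_mean=x_mean,
        y_mean=0.0,
        r2x=float(r2x_comp.sum()),
        r2x_per_component=r2x_comp,
    )


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS, single response)
# ---------------------------------------------------------------------------

def _fit_pls_core(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    n, p = Xc.shape
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    Xr, yr = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < _EPS:
            raise DomainError("response carries no covariance with X (rank exhausted)")
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < _EPS:
            raise DomainError("degenerate component with zero score variance")
        p_a = Xr.T @ t / tt
        q_a = float(yr @ t / tt)
        Xr -= np.outer(t, p_a)
        yr -= q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    return W, P, T, q, Xr, yr


def fit_plsda(
    X: np.ndarray,
    y,
    n_components: int = 2,
    cv_folds: int | None = 10,
    seed: int = 0,
) -> LatentModel:
    """Two-class PLS-DA; components maximise covariance with the centred
    class indicator.  R²Y always reported; Q² and CV-ANOVA p attached when
    ``cv_folds`` is given."""
    X = np.asarray(X, dtype=float)
    y01 = _encode_two_class(y)
    if n_components < 1:
        raise DomainError("n_components must be >= 1")
    x_mean, y_mean = X.mean(axis=0), float(y01.mean())
    Xc, yc = X - x_mean, y01 - y_mean
    ssx, ssy = float(np.sum(Xc**2)), float(np.sum(yc**2))
    W, P, T, q, Xr, yr = _fit_pls_core(Xc, yc, n_components)
    r2x_comp = np.array([float(T[:, a] @ T[:, a]) * float(P[:, a] @ P[:, a]) / ssx
                         for a in range(n_components)])
    model = LatentModel(
        kind="PLSDA",
        weights=W, loadings=P, scores=T, y_loadings=q,
        x_mean=x_mean, y_mean=y_mean,
        r2x=float(r2x_comp.sum()), r2x_per_component=r2x_comp,
        r2y=1.0 - float(yr @ yr) / ssy,
    )
    model.vip = vip(model)
    model.pcorr = _pcorr(Xc, T[:, 0])
    if cv_folds is not None:
        cv = cross_validate(
            lambda Xt, yt: fit_plsda(Xt, yt, n_components, cv_folds=None),
            X, y01, k=cv_folds, seed=seed, n_model_dof=n_components,
        )
        model.q2, model.cv_anova_p = cv.q2, cv.cv_anova_p
    return model


# ---------------------------------------------------------------------------
# OPLS-DA (Trygg & Wold OSC-embedded PLS)
# ---------------------------------------------------------------------------

def fit_oplsda(
    X: np.ndarray,
    y,
    n_orthogonal: int = 1,
    cv_folds: int | None = 10,
    seed: int = 0,
) -> LatentModel:
    """One predictive component plus ``n_orthogonal`` y-orthogonal components.

    The orthogonal scores are exactly uncorrelated with the class indicator by
    construction.  p(corr) is the Pearson correlation of each input variable
    with the predictive score.
    """
    X = np.asarray(X, dtype=float)
    y01 = _encode_two_class(y)
    if n_orthogonal < 0:
        raise DomainError("n_orthogonal must be >= 0")
    n, p = X.shape
    if n_orthogonal > min(n, p) - 1:
        raise DomainError("n_orthogonal exceeds the model rank minus one")
    x_mean, y_mean = X.mean(axis=0), float(y01.mean())
    Xc, yc = X - x_mean, y01 - y_mean
    ssx, ssy = float(np.sum(Xc**2)), float(np.sum(yc**2))

    w = Xc.T @ yc
    norm = np.linalg.norm(w)
    if norm < _EPS:
        raise DomainError("response carries no covariance with X")
    w /= norm

    Xr = Xc.copy()
    W_o = np.empty((p, n_orthogonal))
    P_o = np.empty((p, n_orthogonal))
    T_o = np.empty((n, n_orthogonal))
    for a in range(n_orthogonal):
        t = Xr @ w
        p_a = Xr.T @ t / float(t @ t)
        w_o = p_a - float(w @ p_a) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < _EPS:
            raise DomainError("no orthogonal variation left to extract")
        w_o /= norm_o
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / float(t_o @ t_o)
        Xr -= np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o

    t = Xr @ w
    tt = float(t @ t)
    p_pred = Xr.T @ t / tt
    q = float(yc @ t / tt)

    r2x_pred = tt * float(p_pred @ p_pred) / ssx
    y_res = yc - q * t
    model = LatentModel(
        kind="OPLSDA",
        weights=w[:, None], loadings=p_pred[:, None], scores=t[:, None],
        y_loadings=np.array([q]),
        x_mean=x_mean, y_mean=y_mean,
        r2x=r2x_pred + (
            sum(float(T_o[:, a] @ T_o[:, a]) * float(P_o[:, a] @ P_o[:, a]) for a in range(n_orthogonal)) / ssx
            if n_orthogonal else 0.0
        ),
        r2x_per_component=np.array([r2x_pred]),
        r2y=1.0 - float(y_res @ y_res) / ssy,
        ortho_weights=W_o if n_orthogonal else None,
        ortho_loadings=P_o if n_orthogonal else None,
        ortho_scores=T_o if n_orthogonal else None,
    )
    model.vip = vip(model)
    model.pcorr = _pcorr(Xc, t)
    if cv_folds is not None:
        cv = cross_validate(
            lambda Xt, yt: fit_oplsda(Xt, yt, n_orthogonal, cv_folds=None),
            X, y01, k=cv_folds, seed=seed, n_model_dof=1 + n_orthogonal,
        )
        model.q2, model.cv_anova_p = cv.q2, cv.cv_anova_p
    return model


def _pcorr(Xc: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Correlation of each (centred) variable with the predictive score."""
    t_c = t - t.mean()
    t_norm = np.linalg.norm(t_c)
    col_norm = np.linalg.norm(Xc - Xc.mean(axis=0), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc - Xc.mean(axis=0)).T @ t_c / (col_norm * t_norm)
    return np.where(col_norm < _EPS, 0.0, r)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in projection over the predictive components.

    ``VIP_j = sqrt(p * sum_a SSY_a (w_ja/|w_a|)^2 / sum_a SSY_a)`` with
    ``SSY_a`` the y-variance captured by component a; consequently
    ``sum_j VIP_j^2 = p`` for every fitted model.
    """
    if model.kind == "PCA":
        raise DomainError("VIP is defined for class-predictive models only")
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = np.array([q[a] ** 2 * float(T[:, a] @ T[:, a]) for a in range(W.shape[1])])
    if ssy.sum() < _EPS:
        ssy = np.ones_like(ssy)
    w_norm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (w_norm2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    q2: float
    press: float
    ss: float
    cv_anova_p: float
    predictions: np.ndarray


def _stratified_folds(y01: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified fold assignment; k = n degenerates to leave-one-out."""
    n = y01.size
    fold_of = np.empty(n, dtype=int)
    if k == n:
        fold_of[:] = np.arange(n)
    else:
        for cls in np.unique(y01):
            idx = np.flatnonzero(y01 == cls)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(idx.size) % k
    return [np.flatnonzero(fold_of == f) for f in range(k) if np.any(fold_of == f)]


def cross_validate(
    fitter,
    X: np.ndarray,
    y,
    k: int = 10,
    seed: int = 0,
    n_model_dof: int = 2,
) -> CVResult:
    """Stratified k-fold Q² and CV-ANOVA p for a latent-variable model.

    ``Q² = 1 - PRESS/SS`` with SS the total centred y variation.  The
    CV-ANOVA compares the cross-validated residual variation with the total:
    ``F = ((SS - PRESS)/A) / (PRESS/(N - A - 1))``, A = model degrees of
    freedom; F <= 0 maps to p = 1.  The test is conservative under the null.
    """
    X = np.asarray(X, dtype=float)
    y01 = _encode_two_class(y)
    n = y01.size
    if k < 2:
        raise DomainError("need at least 2 folds")
    if k > n:
        raise DomainError("k cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y01, k, rng)
    pred = np.full(n, np.nan)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        if np.unique(y01[train]).size < 2:
            # a fold swallowed a whole class; predict the training mean
            pred[test_idx] = y01[train].mean()
            continue
        model = fitter(X[train], y01[train])
        pred[test_idx] = model.predict(X[test_idx])
    press = float(np.sum((y01 - pred) ** 2))
    ss = float(np.sum((y01 - y01.mean()) ** 2))
    q2 = 1.0 - press / ss
    A = max(int(n_model_dof), 1)
    d2 = n - A - 1
    if d2 <= 0 or press <= 0:
        p_val = np.nan
    else:
        F = ((ss - press) / A) / (press / d2)
        p_val = float(stats.f.sf(F, A, d2)) if F > 0 else 1.0
    return CVResult(q2=q2, press=press, ss=ss, cv_anova_p=p_val, predictions=pred)


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------

@dataclass
class PermutationReport:
    """Label-permutation validation of a PLS/OPLS model."""

    n_perm: int
    r2_values: np.ndarray
    q2_values: np.ndarray
    correlations: np.ndarray
    r2_original: float
    q2_original: float
    r2_intercept: float
    q2_intercept: float
    valid: bool


def permutation_test(
    X: np.ndarray,
    y,
    n_perm: int = 200,
    n_orthogonal: int = 1,
    cv_folds: int = 10,
    seed: int = 0,
) -> PermutationReport:
    """Refit the OPLS-DA model under uniformly permuted labels.

    For each permutation the model's R²Y and cross-validated Q² are recorded
    together with the absolute correlation between the permuted and original
    labels.  Intercepts come from least-squares regression of R² (and Q²) on
    |correlation| with the original model included as the corr = 1 anchor.
    The model is ``valid`` when every permuted R² and Q² lies below the
    original values and the Q² intercept is negative.  A permutation equal to
    the identity is redrawn (it belongs to the alternative, not the null).
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y01 = _encode_two_class(y)
    rng = np.random.default_rng(seed)

    original = fit_oplsda(X, y01, n_orthogonal, cv_folds=cv_folds, seed=seed)
    r2s, q2s, cors = [], [], []
    yc = y01 - y01.mean()
    y_norm = float(yc @ yc)
    for _ in range(n_perm):
        while True:
            perm = rng.permutation(y01.size)
            if not np.array_equal(y01[perm], y01):
                break
        y_p = y01[perm]
        m = fit_oplsda(X, y_p, n_orthogonal, cv_folds=cv_folds,
                       seed=int(rng.integers(2**31)))
        r2s.append(m.r2y)
        q2s.append(m.q2)
        cors.append(float((y_p - y_p.mean()) @ yc) / y_norm)

    r2s, q2s, cors = map(np.asarray, (r2s, q2s, cors))
    cors_all = np.abs(np.append(cors, 1.0))
    design = np.column_stack([np.ones(cors_all.size), cors_all])
    r2_int = float(np.linalg.lstsq(design, np.append(r2s, original.r2y), rcond=None)[0][0])
    q2_int = float(np.linalg.lstsq(design, np.append(q2s, original.q2), rcond=None)[0][0])
    valid = bool(
        np.all(r2s < original.r2y) and np.all(q2s < original.q2) and q2_int < 0
    )
    return PermutationReport(
        n_perm=n_perm, r2_values=r2s, q2_values=q2s, correlations=cors,
        r2_original=original.r2y, q2_original=original.q2,
        r2_intercept=r2_int, q2_intercept=q2_int, valid=valid,
    )
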