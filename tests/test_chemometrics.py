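"""PCA / PLS-DA / OPLS-DA, VIP, cross-validation and permutation validation."""

import numpy as np
import pytest

import ssmetab.chemometrics as cm
from ssmetab.exceptions import DomainError


def _two_class(n=60):
    return np.repeat([0, 1], n // 2)


def _informative(seed=0, n=60, p=59, shift=1.0, k=5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = _two_class(n)
    X[y == 1, :k] += shift
    return X, y


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_matrix_fully_explained():
    u = np.arange(1.0, 11.0)
    v = np.array([1.0, -2.0, 0.5])
    X = np.outer(u, v)
    model = cm.fit_pca(X, 1)
    assert model.r2x == pytest.approx(1.0, abs=1e-12)


def test_pca_reconstructs_matrix_at_full_rank():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(12, 6))
    model = cm.fit_pca(X, 6)
    recon = model.scores @ model.loadings.T + model.x_mean
    assert np.allclose(recon, X, atol=1e-10)


def test_pca_agrees_with_direct_svd():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(10, 8))
    model = cm.fit_pca(X, 3)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for a in range(3):
        ref = U[:, a] * s[a]
        got = model.scores[:, a]
        assert np.allclose(got, ref) or np.allclose(got, -ref)


def test_pca_rejects_empty_matrix():
    with pytest.raises(DomainError):
        cm.fit_pca(np.empty((0, 0)), 1)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def test_plsda_perfect_single_column_signal():
    y = _two_class(20)
    X = np.zeros((20, 5))
    X[:, 2] = y * 2.0 - 1.0
    model = cm.fit_plsda(X, y, 1, cv_folds=None)
    assert model.r2y == pytest.approx(1.0, abs=1e-10)
    w = np.abs(model.weights[:, 0])
    assert np.argmax(w) == 2 and w[2] > 0.99


def test_plsda_label_permutation_destroys_q2():
    X, y = _informative(seed=3)
    rep = cm.permutation_test(X, y, n_perm=50, n_orthogonal=0, seed=3)
    assert rep.q2_values.mean() <= 0.1
    assert rep.q2_original > 0.3


def test_plsda_rejects_degenerate_inputs():
    X, y = _informative(seed=4, n=20, p=5)
    with pytest.raises(DomainError):
        cm.fit_plsda(X, y, 0)
    with pytest.raises(DomainError):
        cm.fit_plsda(X, np.zeros(20), 1)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

def test_oplsda_without_orthogonal_equals_one_component_plsda():
    X, y = _informative(seed=5)
    pls = cm.fit_plsda(X, y, 1, cv_folds=10, seed=0)
    opls = cm.fit_oplsda(X, y, 0, cv_folds=10, seed=0)
    assert abs(pls.q2 - opls.q2) < 1e-10
    t_p, t_o = pls.scores[:, 0], opls.scores[:, 0]
    assert np.allclose(t_p, t_o) or np.allclose(t_p, -t_o)


def test_oplsda_absorbs_planted_orthogonal_structure():
    """A strong y-orthogonal direction hurts the first PLS component but is
    captured by the orthogonal component of OPLS."""
    rng = np.random.default_rng(6)
    n, p = 80, 40
    y = _two_class(n)
    X = rng.normal(size=(n, p)) * 0.3
    X[y == 1, 0] += 1.0                       # predictive direction
    confound = rng.normal(size=n) * 3.0       # orthogonal, high-variance
    X[:, 1:10] += np.outer(confound, np.ones(9))
    pls1 = cm.fit_plsda(X, y, 1, cv_folds=None)
    opls = cm.fit_oplsda(X, y, 1, cv_folds=None)
    assert opls.r2y > pls1.r2y


def test_oplsda_orthogonal_scores_uncorrelated_with_labels():
    X, y = _informative(seed=7)
    model = cm.fit_oplsda(X, y, 2, cv_folds=None)
    for a in range(model.n_orthogonal):
        r = np.corrcoef(model.ortho_scores[:, a], y)[0, 1]
        assert abs(r) < 1e-8


def test_oplsda_rejects_excessive_orthogonal_components():
    X, y = _informative(seed=8, n=10, p=4)
    with pytest.raises(DomainError):
        cm.fit_oplsda(X, y, 4, cv_folds=None)


# ---------------------------------------------------------------------------
# VIP and p(corr)
# ---------------------------------------------------------------------------

def test_vip_single_variable_is_one():
    y = _two_class(20)
    X = (y * 2.0 - 1.0 + 0.1 * np.random.default_rng(9).normal(size=20))[:, None]
    model = cm.fit_plsda(X, y, 1, cv_folds=None)
    assert model.vip[0] == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("fit", ["pls1", "pls2", "opls"])
def test_vip_squares_sum_to_variable_count(fit):
    X, y = _informative(seed=10, n=40, p=23)
    if fit == "pls1":
        model = cm.fit_plsda(X, y, 1, cv_folds=None)
    elif fit == "pls2":
        model = cm.fit_plsda(X, y, 2, cv_folds=None)
    else:
        model = cm.fit_oplsda(X, y, 1, cv_folds=None)
    assert np.sum(model.vip**2) == pytest.approx(X.shape[1], rel=1e-10)


def test_vip_flags_the_informative_variable():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(60, 50))
    y = _two_class(60)
    X[y == 1, 0] += 1.5
    model = cm.fit_oplsda(X, y, 1, cv_folds=None)
    assert np.argmax(model.vip) == 0
    assert model.vip[0] > 1.0


def test_vip_undefined_for_pca():
    model = cm.fit_pca(np.random.default_rng(12).normal(size=(10, 4)), 2)
    with pytest.raises(DomainError):
        cm.vip(model)


def test_pcorr_bounded_and_signed_by_effect_direction():
    X, y = _informative(seed=13, shift=1.5)
    model = cm.fit_oplsda(X, y, 1, cv_folds=None)
    assert np.all(np.abs(model.pcorr) <= 1.0 + 1e-12)
    # score sign convention aside, the 5 shifted variables agree in sign
    signs = np.sign(model.pcorr[:5])
    assert np.all(signs == signs[0])
    assert np.all(np.abs(model.pcorr[:5]) > 0.4)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_null_data_q2_nonpositive_on_average():
    q2s = []
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(40, 30))
        y = _two_class(40)
        cv = cm.cross_validate(
            lambda a, b: cm.fit_oplsda(a, b, 1, cv_folds=None),
            X, y, k=10, seed=seed, n_model_dof=2,
        )
        q2s.append(cv.q2)
    assert np.mean(q2s) <= 0.0


def test_cv_anova_null_rejection_not_anticonservative():
    """The F-approximation is conservative: null rejections stay below nominal."""
    rejections = 0
    for seed in range(50):
        rng = np.random.default_rng(200 + seed)
        X = rng.normal(size=(60, 30))
        cv = cm.cross_validate(
            lambda a, b: cm.fit_oplsda(a, b, 1, cv_folds=None),
            X, _two_class(60), k=10, seed=seed, n_model_dof=2,
        )
        rejections += cv.cv_anova_p < 0.05
    assert rejections / 50 <= 0.10


def test_perfectly_separable_classes_give_high_q2_and_small_cv_anova_p():
    rng = np.random.default_rng(14)
    y = _two_class(60)
    X = rng.normal(size=(60, 20)) * 0.05
    X[:, 0] = y * 2.0 - 1.0  # noiseless separating direction
    model = cm.fit_oplsda(X, y, 1, cv_folds=10, seed=1)
    assert model.q2 > 0.9
    assert model.cv_anova_p < 1e-6


def test_leave_one_out_runs_and_is_finite():
    X, y = _informative(seed=15, n=16, p=8)
    cv = cm.cross_validate(
        lambda a, b: cm.fit_plsda(a, b, 1, cv_folds=None), X, y, k=16, seed=0,
    )
    assert np.isfinite(cv.q2)


def test_fewer_than_two_folds_rejected():
    X, y = _informative(seed=16, n=10, p=4)
    with pytest.raises(DomainError):
        cm.cross_validate(lambda a, b: cm.fit_plsda(a, b, 1, cv_folds=None),
                          X, y, k=1)


# ---------------------------------------------------------------------------
# permutation validation
# ---------------------------------------------------------------------------

def test_permutation_validates_informative_data():
    rng = np.random.default_rng(17)
    X = rng.normal(size=(60, 59))
    y = _two_class(60)
    X[y == 1, :5] += 2.0  # 2-SD mean shift in 5 variables
    rep = cm.permutation_test(X, y, n_perm=50, seed=17)
    assert rep.valid
    assert rep.q2_intercept < 0


def test_permutation_rarely_validates_pure_noise():
    valid = []
    for seed in range(50):
        rng = np.random.default_rng(300 + seed)
        X = rng.normal(size=(40, 30))
        rep = cm.permutation_test(X, _two_class(40), n_perm=15, cv_folds=5,
                                  seed=seed)
        valid.append(rep.valid)
    assert np.mean(valid) <= 0.10


def test_permutation_never_records_the_identity_relabelling():
    rng = np.random.default_rng(18)
    X = rng.normal(size=(8, 4))
    y = _two_class(8)
    rep = cm.permutation_test(X, y, n_perm=40, cv_folds=2, seed=18)
    # signed corr = +1 occurs only when the relabelling equals the original
    # labels, which the null excludes; the full swap (corr = -1) is allowed
    assert rep.correlations.shape == (40,)
    assert np.all(rep.correlations < 1.0 - 1e-12)
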