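"""Spectral processing: FID path, calibration, bucketing, quantification."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import ssmetab as sm
from ssmetab.exceptions import CalibrationError, ConfigurationError, DomainError
from ssmetab.spectra import bucket_edges, exponential_window, process_fid

from conftest import QUIET


# ---------------------------------------------------------------------------
# FID path
# ---------------------------------------------------------------------------

def _fwhm_hz(spec, sf=600.13):
    i = int(np.argmax(spec.intensity))
    half = spec.intensity[i] / 2.0
    above = np.flatnonzero(spec.intensity >= half)
    seg = above[(above >= i - 500) & (above <= i + 500)]
    return (spec.ppm[seg[-1]] - spec.ppm[seg[0]]) * sf


def test_decaying_sinusoid_gives_lorentzian_broadened_by_lb():
    """Analytic oracle: FWHM = 1/(pi*T2) Hz, plus lb Hz after apodization."""
    sw, n, T2, f0 = 6000.0, 4096, 0.2, 500.0
    t = np.arange(n) / sw
    fid = np.exp(2j * np.pi * f0 * t) * np.exp(-t / T2)
    s0 = process_fid(fid, zero_fill_to=65536, lb=0.0, sw=sw, baseline=False)
    s2 = process_fid(fid, zero_fill_to=65536, lb=2.0, sw=sw, baseline=False)
    natural = 1.0 / (np.pi * T2)
    peak_ppm = s0.ppm[np.argmax(s0.intensity)]
    assert peak_ppm == pytest.approx(4.70 - f0 / 600.13, abs=0.001)
    assert _fwhm_hz(s0) == pytest.approx(natural, rel=0.05)
    assert _fwhm_hz(s2) - _fwhm_hz(s0) == pytest.approx(2.0, rel=0.10)


def test_apodization_window_is_one_at_time_zero():
    for lb in (0.0, 0.3, 1.0, 5.0):
        assert exponential_window(64, 1e-4, lb)[0] == 1.0


def test_zero_fid_gives_zero_spectrum():
    spec = process_fid(np.zeros(64, dtype=complex), zero_fill_to=128, sw=6000.0)
    assert np.all(spec.intensity == 0.0)


def test_negative_line_broadening_rejected():
    with pytest.raises(DomainError):
        process_fid(np.ones(16, dtype=complex), zero_fill_to=32, lb=-1.0, sw=6000.0)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def test_calibration_recovers_planted_global_shift():
    noise = sm.NoiseModel(sigma_log=0, intensity_sd=0.01, baseline_amplitude=0,
                          shift_jitter_sd=0, water_amplitude=0, urea_amplitude=0)
    axis = sm.default_axis()
    step = axis[1] - axis[0]
    base = sm.synthesize_spectrum({"lactate": 2.0}, noise=noise, axis=axis,
                                  rng=np.random.default_rng(0))
    shifted = sm.Spectrum(ppm=base.ppm + 0.01, intensity=base.intensity)
    cal = sm.calibrate(shifted)
    assert cal.calibration_offset == pytest.approx(-0.01, abs=step / 2 + 1e-9)


def test_already_calibrated_spectrum_offset_near_zero():
    spec = sm.synthesize_spectrum({"lactate": 2.0}, noise=QUIET)
    cal = sm.calibrate(spec)
    step = spec.ppm[1] - spec.ppm[0]
    assert abs(cal.calibration_offset) <= step


def test_flat_spectrum_raises_calibration_error():
    flat = sm.Spectrum(ppm=np.linspace(0, 10, 1000), intensity=np.ones(1000))
    with pytest.raises(CalibrationError):
        sm.calibrate(flat)


# ---------------------------------------------------------------------------
# bucketing
# ---------------------------------------------------------------------------

def test_default_bucket_count_is_3445():
    edges = bucket_edges()
    assert len(edges) == 3445
    # anchored at 0.6 on the 0.002 grid
    k = np.round((edges[:, 0] - 0.6) / 0.002)
    assert np.allclose(edges[:, 0], 0.6 + 0.002 * k, atol=1e-12)
    # no bucket overlaps an excluded region
    for lo, hi in ((4.67, 5.20), (5.50, 6.08)):
        assert not np.any((edges[:, 1] > lo + 1e-12) & (edges[:, 0] < hi - 1e-12))


def test_constant_spectrum_gives_equal_buckets():
    spec = sm.Spectrum(ppm=np.linspace(0.2, 9.8, 20001), intensity=np.full(20001, 3.0))
    row, edges = sm.bin_spectrum(spec)
    assert np.allclose(row, 1.0 / 3445, atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_normalized_rows_sum_to_one(seed):
    rng = np.random.default_rng(seed)
    spec = sm.Spectrum(ppm=np.linspace(0.2, 9.8, 16384),
                       intensity=rng.uniform(0.1, 2.0, 16384))
    row, _ = sm.bin_spectrum(spec)
    assert row.sum() == pytest.approx(1.0, abs=1e-9)


def test_bad_bucket_configuration_rejected():
    with pytest.raises(ConfigurationError):
        bucket_edges(width=-0.002)
    with pytest.raises(ConfigurationError):
        bucket_edges(exclusions=((9.0, 9.5),))


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def test_doubled_metabolite_quantifies_near_twofold(quiet_noise):
    """Planting a 2x concentration shows up as a ~2x relative concentration."""
    base = {m.name: m.base_level for m in sm.DEFAULT_LIBRARY}
    doubled = {**base, "succinate": 2 * base["succinate"]}
    specs = [
        sm.synthesize_spectrum(base, noise=quiet_noise, sample_id="a"),
        sm.synthesize_spectrum(doubled, noise=quiet_noise, sample_id="b"),
    ]
    qt = sm.quantify(specs, sm.default_assignment_map())
    ratio = qt.values.loc["b", "succinate"] / qt.values.loc["a", "succinate"]
    assert ratio == pytest.approx(2.0, rel=0.10)


def test_empty_assignment_list_rejected():
    spec = sm.synthesize_spectrum({"alanine": 1.0}, noise=QUIET)
    with pytest.raises(ConfigurationError):
        sm.quantify([spec], {"alanine": []})


def test_assignment_inside_excluded_region_rejected():
    spec = sm.synthesize_spectrum({"alanine": 1.0}, noise=QUIET)
    with pytest.raises(ConfigurationError):
        sm.quantify([spec], {"water": [(4.8, 4.9)]})


def test_two_disjoint_intervals_quantify_additively(quiet_noise):
    spec = sm.synthesize_spectrum({"beta-glucose": 1.0}, noise=quiet_noise,
                                  sample_id="s")
    both = sm.quantify([spec], {"beta-glucose": [(4.60, 4.67), (3.43, 3.51)]})
    first = sm.quantify([spec], {"beta-glucose": [(4.60, 4.67)]})
    second = sm.quantify([spec], {"beta-glucose": [(3.43, 3.51)]})
    assert both.values.iloc[0, 0] == pytest.approx(
        first.values.iloc[0, 0] + second.values.iloc[0, 0], rel=1e-9
    )


def test_quantify_round_trip_tracks_true_concentrations():
    """quantify(synthesize(c)) correlates with c at default noise."""
    design = sm.CohortDesign(seed=3, groups=(("PAC", 60),))
    conc, _, _ = sm.generate_cohort(design)
    spectra = [sm.calibrate(s) for s in sm.synthesize_cohort_spectra(conc, design)]
    qt = sm.quantify(spectra, sm.default_assignment_map())
    rs = np.array([
        spearmanr(conc[m], qt.values[m]).statistic for m in qt.metabolites
    ])
    assert np.median(rs) >= 0.95
    assert rs.min() >= 0.80


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def test_pareto_scaling_divides_by_root_sd():
    col = np.array([0.0, 0.0, 8.0, 8.0, 4.0])  # sample SD = 4 -> divide by 2
    assert np.std(col, ddof=1) == 4.0
    X = np.column_stack([col, np.ones(5)])
    scaled, flags = sm.pareto_scale(X, return_flags=True)
    assert np.allclose(scaled[:, 0], (col - col.mean()) / 2.0)
    assert flags.tolist() == [False, True]
    assert np.all(scaled[:, 1] == 0.0)


def test_pareto_scaled_columns_are_centred_with_sd_variance():
    rng = np.random.default_rng(4)
    X = rng.gamma(2.0, 1.5, size=(50, 8))
    scaled = sm.pareto_scale(X)
    assert np.allclose(scaled.mean(axis=0), 0.0, atol=1e-12)
    # var of the scaled column equals the SD of the original column
    assert np.allclose(scaled.var(axis=0, ddof=1), X.std(axis=0, ddof=1))
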