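"""Spectral processing: FID conversion, calibration, bucketing, quantification.

The canonical entry point of the pipeline is a frequency-domain spectrum (the
synthetic generator emits these directly).  ``process_fid`` offers the optional
time-domain path: exponential apodization, zero-filling, Fourier transform,
automatic phase correction and polynomial baseline correction.

Processed spectra are reduced to two tabular views:

* a :class:`BinMatrix` of uniform 0.002-ppm buckets over δ0.6–8.6 with the
  residual-water (δ4.67–5.20) and urea (δ5.50–6.08) windows removed and each
  row normalised to unit total area, and
* a :class:`QuantTable` of per-metabolite relative concentrations, the
  integral of each metabolite's assigned chemical-shift intervals on the
  total-area-normalised spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize

from .exceptions import CalibrationError, ConfigurationError, DomainError

#: default bucketing parameters
DEFAULT_RANGE: tuple[float, float] = (0.6, 8.6)
DEFAULT_EXCLUSIONS: tuple[tuple[float, float], ...] = ((4.67, 5.20), (5.50, 6.08))
DEFAULT_BIN_WIDTH: float = 0.002
#: chemical shift of the endogenous lactate doublet used for calibration
LACTATE_PPM: float = 1.33


@dataclass
class Spectrum:
    """A 1D spectrum on a strictly ascending ppm grid."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    calibration_offset: float = 0.0

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise DomainError("ppm and intensity must have equal length")
        if self.ppm.ndim != 1 or self.ppm.size < 2:
            raise DomainError("spectrum must be a 1D array of length >= 2")
        if not np.all(np.diff(self.ppm) > 0):
            raise DomainError("ppm axis must be strictly ascending")


@dataclass
class BinMatrix:
    """Samples x uniform-width buckets, with provenance of edges/exclusions."""

    values: np.ndarray
    bin_edges: np.ndarray  # (n_bins, 2) half-open [lo, hi)
    sample_ids: list[str]
    normalized: bool
    excluded_regions: tuple[tuple[float, float], ...]
    width: float = DEFAULT_BIN_WIDTH

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{lo:.3f}" for lo, _ in self.bin_edges]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)

    @property
    def centers(self) -> np.ndarray:
        return self.bin_edges.mean(axis=1)


@dataclass
class QuantTable:
    """Samples x metabolites relative concentrations plus the assignment map."""

    values: pd.DataFrame
    assignment_map: dict[str, list[tuple[float, float]]]

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# FID path
# ---------------------------------------------------------------------------

def exponential_window(n: int, dwell: float, lb: float) -> np.ndarray:
    """Exponential apodization ``exp(-pi * lb * t)``; equals 1 at t=0."""
    if lb < 0:
        raise DomainError("line-broadening factor must be non-negative")
    t = np.arange(n) * dwell
    return np.exp(-np.pi * lb * t)


def _phase(spec: np.ndarray, phi0: float, phi1: float) -> np.ndarray:
    n = spec.size
    ramp = np.arange(n) / n
    return spec * np.exp(1j * (phi0 + phi1 * ramp))


def _phase_objective(params: np.ndarray, spec: np.ndarray) -> float:
    # entropy of the first derivative of the real part, plus a penalty on
    # negative intensity (Chen-style automatic phasing)
    real = _phase(spec, params[0], params[1]).real
    deriv = np.abs(np.diff(real))
    total = deriv.sum()
    if total == 0:
        return 0.0
    h = deriv / total
    entropy = -np.sum(h[h > 0] * np.log(h[h > 0]))
    neg = real[real < 0]
    penalty = np.sum(neg**2) / np.sum(real**2)
    return entropy + 1000.0 * penalty


def autophase(spec: np.ndarray) -> np.ndarray:
    """Zeroth/first-order phase correction by entropy minimisation."""
    best = None
    for phi0 in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
        res = minimize(
            _phase_objective, x0=np.array([phi0, 0.0]), args=(spec,),
            method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    return _phase(spec, best.x[0], best.x[1])


def baseline_correct(intensity: np.ndarray, degree: int = 3, n_iter: int = 10) -> np.ndarray:
    """Iterative polynomial baseline: fit, clip points above the fit, refit."""
    x = np.linspace(-1.0, 1.0, intensity.size)
    y = intensity.astype(float).copy()
    work = y.copy()
    for _ in range(n_iter):
        coef = np.polynomial.polynomial.polyfit(x, work, degree)
        base = np.polynomial.polynomial.polyval(x, coef)
        work = np.minimum(work, base)
    return y - base


def process_fid(
    fid: np.ndarray,
    zero_fill_to: int = 65536,
    lb: float = 1.0,
    sw: float = 12000.0,
    spectrometer_freq: float = 600.13,
    center_ppm: float = 4.70,
    phase: bool = True,
    baseline: bool = True,
) -> Spectrum:
    """Turn a complex FID into a real spectrum.

    Applies the exponential window ``exp(-pi*lb*t)``, zero-fills to
    ``zero_fill_to`` points, Fourier transforms, then (optionally) applies
    automatic phase and polynomial baseline correction.  The ppm axis spans
    ``sw`` Hz around ``center_ppm`` at ``spectrometer_freq`` MHz.
    """
    fid = np.asarray(fid, dtype=complex)
    if zero_fill_to < fid.size:
        raise DomainError("zero_fill_to must be >= the FID length")
    dwell = 1.0 / sw
    windowed = fid * exponential_window(fid.size, dwell, lb)
    padded = np.zeros(zero_fill_to, dtype=complex)
    padded[: fid.size] = windowed
    # first point at half weight avoids a baseline offset from the FFT sum
    padded[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(padded))
    if phase and np.any(np.abs(spec) > 0):
        spec = autophase(spec)
    real = spec.real
    freq = np.fft.fftshift(np.fft.fftfreq(zero_fill_to, d=dwell))
    ppm = center_ppm - freq / spectrometer_freq  # descending in freq
    order = np.argsort(ppm)
    ppm, real = ppm[order], real[order]
    if baseline and np.any(real != 0):
        real = baseline_correct(real)
    return Spectrum(ppm=ppm, intensity=real)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate(
    spec: Spectrum,
    reference: float = LACTATE_PPM,
    search_window: float = 0.04,
    snr_min: float = 5.0,
) -> Spectrum:
    """Shift the ppm axis so the reference doublet centroid sits at ``reference``.

    The detected position is the intensity-weighted centroid of all points in
    the search window above half the window maximum, which lands midway
    between the two lines of a doublet.  Raises :class:`CalibrationError` when
    no peak rises ``snr_min`` times above the spectrum's noise floor.
    """
    lo, hi = reference - search_window, reference + search_window
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    if not np.any(mask):
        raise CalibrationError("search window outside the spectrum")
    window = spec.intensity[mask]
    ppm_w = spec.ppm[mask]
    noise = 1.4826 * np.median(np.abs(spec.intensity - np.median(spec.intensity)))
    peak = window.max()
    prominence = peak - float(np.median(spec.intensity))
    if prominence <= 0 or (noise > 0 and prominence < snr_min * noise):
        raise CalibrationError("no reference peak above the noise floor")
    strong = window >= 0.5 * peak
    centroid = float(np.sum(ppm_w[strong] * window[strong]) / np.sum(window[strong]))
    offset = reference - centroid
    return replace(
        spec,
        ppm=spec.ppm + offset,
        calibration_offset=spec.calibration_offset + offset,
    )


# ---------------------------------------------------------------------------
# bucketing and normalisation
# ---------------------------------------------------------------------------

def bucket_edges(
    ppm_range: tuple[float, float] = DEFAULT_RANGE,
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
    width: float = DEFAULT_BIN_WIDTH,
) -> np.ndarray:
    """Half-open bucket edges on the ``start + k*width`` grid, minus exclusions.

    A bucket is kept when it does not overlap any excluded interval.  For the
    study's range, exclusions and width this yields exactly 3445 buckets.
    """
    if width <= 0:
        raise ConfigurationError("bucket width must be positive")
    lo, hi = ppm_range
    for e_lo, e_hi in exclusions:
        if e_hi <= lo or e_lo >= hi:
            raise ConfigurationError(f"exclusion ({e_lo}, {e_hi}) outside the range")
    n = int(round((hi - lo) / width))
    starts = lo + width * np.arange(n)
    ends = starts + width
    keep = np.ones(n, dtype=bool)
    for e_lo, e_hi in exclusions:
        keep &= (ends <= e_lo + 1e-12) | (starts >= e_hi - 1e-12)
    return np.column_stack([starts[keep], ends[keep]])


def _segment_integrals(spec: Spectrum, edges: np.ndarray) -> np.ndarray:
    """Trapezoid integral of the spectrum over each [lo, hi) interval."""
    cum = np.concatenate([[0.0], cumulative_trapezoid(spec.intensity, spec.ppm)])
    at = np.interp(edges.ravel(), spec.ppm, cum)
    at = at.reshape(edges.shape)
    return at[:, 1] - at[:, 0]


def bin_spectrum(
    spec: Spectrum,
    ppm_range: tuple[float, float] = DEFAULT_RANGE,
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
    width: float = DEFAULT_BIN_WIDTH,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one spectrum into buckets; returns (row, edges).

    Exclusion is applied before normalisation: the row is divided by the sum
    over the kept buckets only, so each normalised row sums to 1.
    """
    if spec.ppm[0] > ppm_range[0] or spec.ppm[-1] < ppm_range[1]:
        raise DomainError("spectrum does not cover the bucketing range")
    edges = bucket_edges(ppm_range, exclusions, width)
    row = _segment_integrals(spec, edges)
    if normalize:
        total = row.sum()
        if total == 0:
            raise DomainError("cannot normalise an all-zero spectrum")
        row = row / total
    return row, edges


def bin_spectra(
    spectra: list[Spectrum],
    ppm_range: tuple[float, float] = DEFAULT_RANGE,
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
    width: float = DEFAULT_BIN_WIDTH,
    normalize: bool = True,
) -> BinMatrix:
    """Bucket a set of spectra into a :class:`BinMatrix`."""
    rows, edges = [], None
    for spec in spectra:
        row, edges = bin_spectrum(spec, ppm_range, exclusions, width, normalize)
        rows.append(row)
    return BinMatrix(
        values=np.array(rows),
        bin_edges=edges,
        sample_ids=[s.sample_id for s in spectra],
        normalized=normalize,
        excluded_regions=tuple(exclusions),
        width=width,
    )


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for lo, hi in ordered[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(iv) for iv in merged]


def _validate_assignment(
    assignment_map: dict[str, list[tuple[float, float]]],
    ppm_range: tuple[float, float],
    exclusions: tuple[tuple[float, float], ...],
) -> dict[str, list[tuple[float, float]]]:
    clean: dict[str, list[tuple[float, float]]] = {}
    for met, intervals in assignment_map.items():
        if not intervals:
            raise ConfigurationError(f"{met}: empty assignment interval list")
        for lo, hi in intervals:
            if hi <= lo:
                raise ConfigurationError(f"{met}: empty interval ({lo}, {hi})")
            if lo < ppm_range[0] or hi > ppm_range[1]:
                raise ConfigurationError(f"{met}: interval ({lo}, {hi}) outside the range")
            for e_lo, e_hi in exclusions:
                if lo < e_hi and hi > e_lo:
                    raise ConfigurationError(
                        f"{met}: interval ({lo}, {hi}) overlaps excluded region ({e_lo}, {e_hi})"
                    )
        clean[met] = _merge_intervals(list(intervals))
    return clean


def quantify(
    spectra: list[Spectrum],
    assignment_map: dict[str, list[tuple[float, float]]],
    ppm_range: tuple[float, float] = DEFAULT_RANGE,
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
) -> QuantTable:
    """Per-metabolite integrals of the total-area-normalised spectra.

    Each metabolite's relative concentration is the integral of the spectrum
    over its assigned intervals divided by the integral over the full kept
    range, i.e. the quantity a bucket-level analysis would sum over the
    metabolite's buckets.  Overlapping intervals of one metabolite are merged.
    """
    amap = _validate_assignment(assignment_map, ppm_range, exclusions)
    mets = list(amap)
    rows = np.empty((len(spectra), len(mets)))
    kept = _included_segments(ppm_range, exclusions)
    for i, spec in enumerate(spectra):
        total = _segment_integrals(spec, kept).sum()
        if total == 0:
            raise DomainError(f"{spec.sample_id}: zero total area")
        for j, met in enumerate(mets):
            edges = np.array(amap[met], dtype=float)
            rows[i, j] = _segment_integrals(spec, edges).sum() / total
    frame = pd.DataFrame(rows, index=[s.sample_id for s in spectra], columns=mets)
    return QuantTable(values=frame, assignment_map=amap)


def _included_segments(
    ppm_range: tuple[float, float],
    exclusions: tuple[tuple[float, float], ...],
) -> np.ndarray:
    """The kept sub-intervals of the range after removing exclusions."""
    segments = []
    cursor = ppm_range[0]
    for e_lo, e_hi in sorted(exclusions):
        if e_lo > cursor:
            segments.append((cursor, min(e_lo, ppm_range[1])))
        cursor = max(cursor, e_hi)
    if cursor < ppm_range[1]:
        segments.append((cursor, ppm_range[1]))
    return np.array(segments, dtype=float)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def pareto_scale(matrix: np.ndarray, return_flags: bool = False):
    """Pareto scaling: centre each column and divide by sqrt(its SD).

    Zero-variance columns are set to 0 and flagged rather than raising.  The
    scaled column variance equals the SD of the original column.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DomainError("need a 2D matrix with at least two samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    denom = np.sqrt(np.where(degenerate, 1.0, sd))
    scaled = (X - mean) / denom
    scaled[:, degenerate] = 0.0
    if return_flags:
        return scaled, degenerate
    return scaled
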