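"""Synthetic six-group serum cohorts with ground truth.

The generator emulates the study conditions of a pediatric short-stature
cohort: two control groups (preadolescent PAC, adolescent ADC) and four
disease groups (PAG/PAI preadolescent GHD/ISS, ADG/ADI adolescent GHD/ISS)
with sizes 88/94/61/40/43/19, per-group age and sex models, planted
fold-change effects on a configurable subset of metabolites, and mild
age/sex nuisance effects so covariate correction is exercised.

Concentrations are log-normal around ``base_level * fold_change``; spectra are
sums of Lorentzian multiplets plus baseline drift, residual water/urea humps,
additive Gaussian noise and a per-sample global chemical-shift offset.
Everything is reproducible from the design seed, and a
:class:`GroundTruthManifest` records the truth every downstream stage is
scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb

from .exceptions import ConfigurationError, DomainError
from .library import (
    CONTROL_OF,
    DEFAULT_COVARIATE_EFFECTS,
    DEFAULT_COVARIATE_MODEL,
    DEFAULT_EFFECTS,
    DEFAULT_GROUP_SIZES,
    DEFAULT_LIBRARY,
    DEFAULT_PLANTED,
    MetaboliteSpec,
)
from .spectra import Spectrum

#: age (years) at which nuisance age slopes are anchored
REFERENCE_AGE = 9.0


@dataclass(frozen=True)
class NoiseModel:
    """Noise and nuisance amplitudes of the generator.

    ``sigma_log`` is the biological log-scale SD of concentrations (0.20
    corresponds to a ~20% coefficient of variation, typical of serum NMR
    metabolites).  The spectral terms are in spectrum intensity units where a
    concentration of 1 produces a unit-area resonance.
    """

    sigma_log: float = 0.20
    intensity_sd: float = 0.05
    baseline_amplitude: float = 0.10
    shift_jitter_sd: float = 0.003
    water_amplitude: float = 30.0
    urea_amplitude: float = 8.0

    def __post_init__(self) -> None:
        if self.shift_jitter_sd < 0:
            raise ConfigurationError("shift_jitter_sd must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """Everything needed to generate one cohort deterministically."""

    groups: tuple[tuple[str, int], ...] = tuple(DEFAULT_GROUP_SIZES.items())
    effects: dict[str, dict[str, float]] = field(default_factory=lambda: DEFAULT_EFFECTS)
    covariate_model: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_MODEL
    )
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_EFFECTS
    )
    noise: NoiseModel = NoiseModel()
    seed: int = 0
    library: tuple[MetaboliteSpec, ...] = DEFAULT_LIBRARY
    planted: dict[tuple[str, str], frozenset[str]] = field(
        default_factory=lambda: DEFAULT_PLANTED
    )

    def __post_init__(self) -> None:
        names = {m.name for m in self.library}
        for label, n in self.groups:
            if n <= 0:
                raise ConfigurationError(f"group {label} has non-positive size {n}")
        for group, fc_map in self.effects.items():
            for met, fc in fc_map.items():
                if met not in names:
                    raise ConfigurationError(f"unknown metabolite in effects map: {met}")
                if fc <= 0:
                    raise ConfigurationError(f"fold change must be positive: {met}={fc}")
        for contrast, mets in self.planted.items():
            unknown = set(mets) - names
            if unknown:
                raise ConfigurationError(f"planted set {contrast} not in library: {unknown}")


@dataclass
class GroundTruthManifest:
    """True concentrations, covariates and planted sets of one cohort."""

    concentrations: pd.DataFrame  # samples x metabolites, true values
    covariates: pd.DataFrame      # sample_id, group, age, sex
    planted: dict[tuple[str, str], frozenset[str]]
    seed: int


def generate_cohort(
    design: CohortDesign,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruthManifest]:
    """Draw one cohort: (ConcentrationTable, ClinicalTable, manifest).

    Concentrations are drawn log-normally around
    ``base_level * fold_change(group)`` with the nuisance age/sex shifts of
    the design applied on the log scale.  The clinical table carries group,
    age in years and sex (1 = male).
    """
    rng = np.random.default_rng(design.seed)
    mets = [m.name for m in design.library]
    base = np.array([m.base_level for m in design.library])

    ids: list[str] = []
    rows: list[np.ndarray] = []
    clin_rows: list[dict] = []
    for label, n in design.groups:
        if label not in design.covariate_model:
            raise ConfigurationError(f"no covariate model for group {label}")
        age_mean, age_sd, male_frac = design.covariate_model[label]
        ages = np.clip(rng.normal(age_mean, age_sd, size=n), 2.0, 18.0)
        sexes = (rng.random(n) < male_frac).astype(int)
        fc = np.array([design.effects.get(label, {}).get(m, 1.0) for m in mets])
        log_mu = np.log(base * fc)
        for i in range(n):
            sid = f"{label}_{i + 1:03d}"
            shift = np.zeros(len(mets))
            for j, met in enumerate(mets):
                slope, sex_delta = design.covariate_effects.get(met, (0.0, 0.0))
                shift[j] = slope * (ages[i] - REFERENCE_AGE) + sex_delta * sexes[i]
            conc = np.exp(log_mu + shift + rng.normal(0.0, design.noise.sigma_log, len(mets)))
            ids.append(sid)
            rows.append(conc)
            clin_rows.append({"sample_id": sid, "group": label, "age": ages[i], "sex": int(sexes[i])})

    conc_table = pd.DataFrame(rows, index=ids, columns=mets)
    clinical = pd.DataFrame(clin_rows).set_index("sample_id")
    manifest = GroundTruthManifest(
        concentrations=conc_table.copy(),
        covariates=clinical.copy(),
        planted=dict(design.planted),
        seed=design.seed,
    )
    return conc_table, clinical, manifest


# ---------------------------------------------------------------------------
# spectrum synthesis
# ---------------------------------------------------------------------------

def default_axis(lo: float = 0.2, hi: float = 9.8, n: int = 16384) -> np.ndarray:
    """Default ascending ppm grid (~0.0006 ppm step), covering δ0.5-9.0."""
    return np.linspace(lo, hi, n)


def _line_weights(n_lines: int) -> np.ndarray:
    # binomial multiplet intensities (1, 1:1, 1:2:1, ...)
    w = comb(n_lines - 1, np.arange(n_lines))
    return w / w.sum()


def _lorentzian(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return (gamma / np.pi) / ((axis - center) ** 2 + gamma**2)


def _gaussian_hump(axis: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((axis - center) / width) ** 2)


def synthesize_spectrum(
    concentrations: dict[str, float],
    library: tuple[MetaboliteSpec, ...] = DEFAULT_LIBRARY,
    noise: NoiseModel = NoiseModel(),
    axis: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> Spectrum:
    """Render one spectrum from metabolite concentrations.

    Peak area is proportional to ``concentration * relative_area`` per
    multiplet, split across multiplet lines with binomial weights.  The whole
    spectrum is shifted by one global offset drawn with ``shift_jitter_sd``;
    residual water (δ4.67-5.20) and urea (δ5.50-6.08) humps, a slow baseline
    drift and additive Gaussian noise complete the raw look.
    """
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, dtype=float)
    if not np.all(np.diff(axis) > 0):
        raise DomainError("axis must be strictly ascending")
    if axis[0] > 0.5 or axis[-1] < 9.0:
        raise DomainError("axis must cover at least 0.5-9.0 ppm")
    index = {m.name: m for m in library}
    for met, conc in concentrations.items():
        if conc < 0:
            raise DomainError(f"negative concentration for {met}")
        if met not in index:
            raise ConfigurationError(f"unknown metabolite: {met}")

    rng = rng if rng is not None else np.random.default_rng(0)
    offset = rng.normal(0.0, noise.shift_jitter_sd) if noise.shift_jitter_sd > 0 else 0.0

    intensity = np.zeros_like(axis)
    for met, conc in concentrations.items():
        if conc == 0:
            continue
        spec = index[met]
        for center, rel_area, n_lines, spacing in spec.multiplets:
            weights = _line_weights(n_lines)
            start = center - spacing * (n_lines - 1) / 2.0
            for k in range(n_lines):
                area = conc * rel_area * weights[k]
                intensity += area * _lorentzian(axis, start + spacing * k + offset, spec.linewidth)

    if noise.water_amplitude > 0:
        intensity += noise.water_amplitude * _gaussian_hump(axis, 4.93 + offset, 0.10)
    if noise.urea_amplitude > 0:
        intensity += noise.urea_amplitude * _gaussian_hump(axis, 5.79 + offset, 0.09)
    if noise.baseline_amplitude > 0:
        # slow drift: random low-frequency cosine plus a tilt
        phase = rng.uniform(0, 2 * np.pi)
        amp = noise.baseline_amplitude * rng.uniform(0.5, 1.0)
        tilt = noise.baseline_amplitude * rng.uniform(-0.5, 0.5)
        span = axis[-1] - axis[0]
        intensity += amp * (1 + np.cos(2 * np.pi * (axis - axis[0]) / span + phase)) / 2
        intensity += tilt * (axis - axis[0]) / span
    if noise.intensity_sd > 0:
        intensity += rng.normal(0.0, noise.intensity_sd, axis.size)

    return Spectrum(ppm=axis, intensity=intensity, sample_id=sample_id)


def synthesize_cohort_spectra(
    conc_table: pd.DataFrame,
    design: CohortDesign,
    axis: np.ndarray | None = None,
) -> list[Spectrum]:
    """Render one spectrum per row of the concentration table.

    Per-sample RNG streams are spawned from the design seed so the result is
    independent of rendering order.
    """
    if axis is None:
        axis = default_axis()
    root = np.random.SeedSequence(entropy=design.seed, spawn_key=(1,))
    children = root.spawn(len(conc_table))
    spectra = []
    for (sid, row), child in zip(conc_table.iterrows(), children):
        spectra.append(
            synthesize_spectrum(
                row.to_dict(),
                library=design.library,
                noise=design.noise,
                axis=axis,
                rng=np.random.default_rng(child),
                sample_id=str(sid),
            )
        )
    return spectra
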