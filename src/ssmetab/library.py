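"""Bundled serum metabolite library and the default six-group cohort design.

The library lists ~48 metabolites commonly quantifiable in CPMG serum spectra.
Each entry carries one or more multiplets (center, relative area, number of
lines, line spacing), a Lorentzian linewidth, and a baseline serum level in
arbitrary relative-concentration units.  Chemical shifts follow standard
reference values; they are configuration, not assertions about any instrument.

The first multiplet of each metabolite is its *assignment* resonance: it is
chosen to be resolvable from every other metabolite's assignment resonance, and
it is the region integrated by default when converting spectra to relative
concentrations.  Secondary multiplets add realistic spectral crowding.

Broad macromolecule envelopes (VLDL, lipid, N-acetyl glycoprotein) are modelled
as extra-broad single resonances.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# 7 Hz scalar coupling at 600 MHz, in ppm
J = 0.0117
#: default Lorentzian full width at half maximum, ppm (~1.5 Hz at 600 MHz)
DEFAULT_LINEWIDTH = 0.0025


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite of the synthetic library.

    Parameters
    ----------
    name:
        Metabolite identifier used throughout the pipeline.
    multiplets:
        Tuples ``(center_ppm, relative_area, n_lines, line_spacing_ppm)``.
        Relative areas must sum to 1; the first multiplet is the assignment
        resonance used for quantification.
    linewidth:
        Lorentzian FWHM in ppm.
    base_level:
        Baseline serum level in arbitrary concentration units.
    """

    name: str
    multiplets: tuple[tuple[float, float, int, float], ...]
    linewidth: float = DEFAULT_LINEWIDTH
    base_level: float = 0.1

    def __post_init__(self) -> None:
        total = sum(m[1] for m in self.multiplets)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: multiplet relative areas sum to {total}, not 1")
        for center, _, _, _ in self.multiplets:
            if not 0.0 <= center <= 10.0:
                raise ValueError(f"{self.name}: multiplet center {center} outside [0, 10] ppm")
        if self.linewidth <= 0:
            raise ValueError(f"{self.name}: linewidth must be positive")


def _m(center: float, area: float = 1.0, n: int = 1, spacing: float = J):
    return (center, area, n, spacing if n > 1 else 0.0)


#: the bundled library. Assignment (first) multiplets are mutually resolved.
DEFAULT_LIBRARY: tuple[MetaboliteSpec, ...] = (
    # broad macromolecule envelopes
    MetaboliteSpec("vldl", (_m(0.85),), linewidth=8 * DEFAULT_LINEWIDTH, base_level=1.5),
    MetaboliteSpec("lipid", (_m(1.26),), linewidth=8 * DEFAULT_LINEWIDTH, base_level=2.5),
    MetaboliteSpec("n-acetyl-glycoprotein", (_m(2.04),), linewidth=4 * DEFAULT_LINEWIDTH, base_level=1.2),
    # branched-chain and other aliphatic amino acids
    MetaboliteSpec("isoleucine", (_m(0.93, 0.6, 3), _m(1.01, 0.4, 2)), base_level=0.30),
    MetaboliteSpec("leucine", (_m(0.96, 0.7, 3), _m(1.70, 0.3, 2)), base_level=0.55),
    MetaboliteSpec("valine", (_m(0.99, 0.5, 2), _m(1.04, 0.5, 2)), base_level=0.60),
    MetaboliteSpec("isobutyrate", (_m(1.13, 1.0, 2),), base_level=0.15),
    MetaboliteSpec("3-hydroxybutyrate", (_m(1.20, 1.0, 2),), base_level=0.35),
    MetaboliteSpec("lactate", (_m(1.33, 0.75, 2), _m(4.11, 0.25, 2)), base_level=2.0),
    MetaboliteSpec("alanine", (_m(1.48, 1.0, 2),), base_level=0.45),
    MetaboliteSpec("arginine", (_m(1.68, 1.0, 2),), base_level=0.25),
    MetaboliteSpec("lysine", (_m(1.72, 0.6, 2), _m(3.02, 0.4, 3)), base_level=0.40),
    MetaboliteSpec("ornithine", (_m(1.80, 1.0, 2),), base_level=0.18),
    MetaboliteSpec("acetate", (_m(1.92),), base_level=0.30),
    MetaboliteSpec("glutamate", (_m(2.35, 0.6, 2), _m(2.10, 0.4, 2)), base_level=0.30),
    MetaboliteSpec("methionine", (_m(2.64, 0.6, 3), _m(2.13, 0.4, 1)), base_level=0.12),
    # ketone bodies and small organic acids
    MetaboliteSpec("acetone", (_m(2.23),), base_level=0.10),
    MetaboliteSpec("acetoacetate", (_m(2.28),), base_level=0.12),
    MetaboliteSpec("pyruvate", (_m(2.38),), base_level=0.15),
    MetaboliteSpec("succinate", (_m(2.41),), base_level=0.10),
    MetaboliteSpec("glutamine", (_m(2.45, 0.6, 2), _m(2.14, 0.4, 2)), base_level=0.55),
    MetaboliteSpec("citrate", (_m(2.54, 1.0, 2, 0.0267),), base_level=0.20),
    MetaboliteSpec("aspartate", (_m(2.80, 0.6, 2), _m(2.68, 0.4, 2)), base_level=0.15),
    MetaboliteSpec("dimethylamine", (_m(2.72),), base_level=0.08),
    MetaboliteSpec("asparagine", (_m(2.86, 1.0, 2),), base_level=0.12),
    MetaboliteSpec("trimethylamine", (_m(2.91),), base_level=0.06),
    MetaboliteSpec("dimethylglycine", (_m(2.93),), base_level=0.05),
    # methylamines, cholines, sugars
    MetaboliteSpec("creatine", (_m(3.93, 0.4), _m(3.03, 0.6)), base_level=0.30),
    MetaboliteSpec("creatinine", (_m(4.06, 0.4), _m(3.05, 0.6)), base_level=0.25),
    MetaboliteSpec("ethanolamine", (_m(3.14, 1.0, 3),), base_level=0.10),
    MetaboliteSpec("choline", (_m(3.20),), base_level=0.25),
    MetaboliteSpec("phosphocholine", (_m(3.23),), base_level=0.20),
    MetaboliteSpec("trimethylamine-n-oxide", (_m(3.27),), base_level=0.15),
    MetaboliteSpec("methanol", (_m(3.36),), base_level=0.08),
    MetaboliteSpec("taurine", (_m(3.42, 1.0, 3),), base_level=0.25),
    MetaboliteSpec("glycine", (_m(3.55),), base_level=0.25),
    MetaboliteSpec("glycerol", (_m(3.65, 0.6, 2), _m(3.78, 0.4, 2)), base_level=0.50),
    MetaboliteSpec("serine", (_m(3.83, 1.0, 2),), base_level=0.20),
    MetaboliteSpec("beta-glucose", (_m(4.64, 0.35, 2, 0.0063), _m(3.47, 0.65, 2)), base_level=2.8),
    MetaboliteSpec("alpha-glucose", (_m(5.23, 0.35, 2, 0.0063), _m(3.70, 0.65, 2)), base_level=1.6),
    MetaboliteSpec("threonine", (_m(4.25, 1.0, 2),), base_level=0.15),
    # aromatic region
    MetaboliteSpec("fumarate", (_m(6.52),), base_level=0.03),
    MetaboliteSpec("tyrosine", (_m(6.89, 0.5, 2, 0.013), _m(7.19, 0.5, 2, 0.013)), base_level=0.10),
    MetaboliteSpec("histidine", (_m(7.08, 0.5), _m(7.83, 0.5)), base_level=0.10),
    MetaboliteSpec("phenylalanine", (_m(7.37, 1.0, 2, 0.013),), base_level=0.10),
    MetaboliteSpec("tryptophan", (_m(7.54, 1.0, 2, 0.013),), base_level=0.05),
    MetaboliteSpec("hypoxanthine", (_m(8.19),), base_level=0.04),
    MetaboliteSpec("formate", (_m(8.46),), base_level=0.04),
)

LIBRARY_INDEX: dict[str, MetaboliteSpec] = {m.name: m for m in DEFAULT_LIBRARY}


def default_assignment_map(
    library: tuple[MetaboliteSpec, ...] = DEFAULT_LIBRARY,
    tail_width: float = 3.0,
    max_halfwidth: float = 0.045,
) -> dict[str, list[tuple[float, float]]]:
    """Derive per-metabolite integration intervals from assignment resonances.

    The interval spans the assignment multiplet plus ``tail_width`` linewidths
    on either side, capped at ``max_halfwidth`` so broad envelopes do not
    swallow their neighbours.
    """
    amap: dict[str, list[tuple[float, float]]] = {}
    for met in library:
        center, _, n_lines, spacing = met.multiplets[0]
        span = (n_lines - 1) * spacing / 2.0
        half = min(span + tail_width * met.linewidth, max_halfwidth)
        amap[met.name] = [(center - half, center + half)]
    return amap


# ---------------------------------------------------------------------------
# Default cohort design: six groups, planted effects per disease group
# ---------------------------------------------------------------------------

#: group sizes of the study cohort (controls and patients, by stage)
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "PAC": 88, "PAG": 94, "PAI": 61, "ADC": 40, "ADG": 43, "ADI": 19,
}

#: control group for each disease group
CONTROL_OF: dict[str, str] = {"PAG": "PAC", "PAI": "PAC", "ADG": "ADC", "ADI": "ADC"}

#: the six pairwise contrasts analysed by the pipeline, (case, control)
DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("PAG", "PAC"), ("PAI", "PAC"), ("PAI", "PAG"),
    ("ADG", "ADC"), ("ADI", "ADC"), ("ADI", "ADG"),
)

# Planted fold changes vs the group's own control.  Directions follow the
# reported serum changes: preadolescent disease lowers the macromolecule
# envelopes and lactate while raising glycerol, the glucose anomers, ketone
# bodies, succinate, acetate and the cholines; adolescent disease lowers
# branched-chain amino acids, glutamine, lysine, methionine and creatine, with
# additional amino-acid decreases unique to adolescent ISS.
_PRE_SHARED = {
    "vldl": 0.70, "lipid": 0.72, "n-acetyl-glycoprotein": 0.75, "lactate": 0.80,
    "glycerol": 1.35, "alpha-glucose": 1.30, "beta-glucose": 1.30,
    "3-hydroxybutyrate": 1.40, "succinate": 1.35, "acetate": 1.30,
}
_ADO_SHARED = {
    "creatine": 0.75, "glutamine": 0.72, "isoleucine": 0.75, "leucine": 0.75,
    "lysine": 0.72, "methionine": 0.75, "valine": 0.75,
}

DEFAULT_EFFECTS: dict[str, dict[str, float]] = {
    "PAG": {
        **_PRE_SHARED,
        "acetoacetate": 1.35, "acetone": 1.40, "choline": 1.30, "phosphocholine": 1.40,
        # weak effects that matter only for the PAG-vs-PAI comparison
        "aspartate": 1.10, "ethanolamine": 1.10, "trimethylamine": 1.10,
    },
    "PAI": {
        **_PRE_SHARED,
        "phosphocholine": 1.15,
        "aspartate": 0.90, "ethanolamine": 0.90, "trimethylamine": 0.90,
    },
    "ADG": {
        **_ADO_SHARED,
        "acetoacetate": 1.35, "creatinine": 0.80,
        # weak effects that matter only for the ADG-vs-ADI comparison
        "histidine": 1.12, "isobutyrate": 1.12, "methanol": 0.89, "phosphocholine": 1.12,
    },
    "ADI": {
        **_ADO_SHARED,
        "alanine": 0.75, "asparagine": 0.75, "glutamate": 0.75, "glycine": 0.75,
        "lactate": 0.80, "ornithine": 0.75, "pyruvate": 0.75, "trimethylamine-n-oxide": 0.78,
        "histidine": 0.90, "isobutyrate": 0.90, "methanol": 1.10, "phosphocholine": 0.90,
    },
}

#: intended biomarker sets per contrast (metabolites planted at full strength;
#: weak split effects below the joint screen criteria are deliberately absent
#: from the vs-control sets and present in the between-disease sets)
DEFAULT_PLANTED: dict[tuple[str, str], frozenset[str]] = {
    ("PAG", "PAC"): frozenset(_PRE_SHARED) | {"acetoacetate", "acetone", "choline", "phosphocholine"},
    ("PAI", "PAC"): frozenset(_PRE_SHARED) | {"phosphocholine"},
    ("PAI", "PAG"): frozenset({
        "aspartate", "ethanolamine", "trimethylamine", "phosphocholine",
        "acetoacetate", "acetone", "choline",
    }),
    ("ADG", "ADC"): frozenset(_ADO_SHARED) | {"acetoacetate", "creatinine"},
    ("ADI", "ADC"): frozenset(_ADO_SHARED) | {
        "alanine", "asparagine", "glutamate", "glycine", "lactate",
        "ornithine", "pyruvate", "trimethylamine-n-oxide",
    },
    ("ADI", "ADG"): frozenset({
        "histidine", "isobutyrate", "methanol", "phosphocholine", "acetoacetate",
        "creatinine", "alanine", "asparagine", "glutamate", "glycine", "lactate",
        "ornithine", "pyruvate", "trimethylamine-n-oxide",
    }),
}

#: per-group age model (mean years, SD years) and male proportion
DEFAULT_COVARIATE_MODEL: dict[str, tuple[float, float, float]] = {
    "PAC": (7.06, 2.57, 0.625),
    "PAG": (7.38, 2.18, 0.649),
    "PAI": (7.41, 2.56, 0.508),
    "ADC": (11.63, 1.66, 0.525),
    "ADG": (12.00, 1.51, 0.651),
    "ADI": (12.83, 1.74, 0.842),
}

#: mild nuisance effects of covariates on log-concentrations:
#: metabolite -> (slope per year of age, additive shift for males)
DEFAULT_COVARIATE_EFFECTS: dict[str, tuple[float, float]] = {
    "creatinine": (0.025, 0.08),
    "creatine": (0.0, -0.08),
    "alpha-glucose": (0.008, 0.0),
    "beta-glucose": (0.008, 0.0),
    "citrate": (0.0, 0.06),
    "taurine": (0.010, 0.0),
}
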