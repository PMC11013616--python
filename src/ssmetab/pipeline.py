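"""End-to-end pipeline driver: cohort -> spectra -> screens -> models -> ORA.

A run is fully determined by a :class:`PipelineConfig` (JSON/YAML-loadable).
Every random stage draws from a named sub-seed spawned from the config seed,
recorded in ``provenance.json`` together with the config hash and a digest of
every output file, so two runs with the same config are file-identical and
stages can be re-run independently against cached inputs.

Run-directory layout::

    run/
      concentrations.csv  clinical.csv  manifest.json
      bins.csv  bins.meta.json  quant.csv  quant.meta.json
      <CASE>_vs_<CTRL>/
        screen.csv  volcano.csv  model.json  permutation.json
        diagnostics.json  roc_<clf>.csv  ora.csv  network.csv
      provenance.json  pipeline.log
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortDesign, NoiseModel, generate_cohort, synthesize_cohort_spectra
from .chemometrics import permutation_test
from .diagnostics import diagnose_contrast
from .enrich import default_catalog, ora
from .exceptions import ConfigurationError, SSMetabError
from .library import DEFAULT_CONTRASTS, default_assignment_map
from .screen import correlation_network, screen_contrast
from .spectra import (
    DEFAULT_BIN_WIDTH,
    DEFAULT_EXCLUSIONS,
    DEFAULT_RANGE,
    bin_spectra,
    calibrate,
    pareto_scale,
    quantify,
    QuantTable,
)

logger = logging.getLogger("ssmetab")

STAGES = ("simulate", "preprocess", "screen", "diagnose", "enrich")


@dataclass
class PipelineConfig:
    """All knobs of one run; defaults reproduce the study conditions."""

    seed: int = 0
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    ppm_range: tuple[float, float] = DEFAULT_RANGE
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS
    bin_width: float = DEFAULT_BIN_WIDTH
    # screening
    vip_percentile: float = 90.0
    vip_reference: str = "bins"
    p_threshold: float = 0.05
    n_orthogonal: int = 1
    n_permutations: int = 200
    cv_folds: int = 10
    # diagnostics
    classifiers: tuple[str, ...] = ("rf", "lr", "svm")
    scheme: str = "cv"
    diag_folds: int = 5
    n_boot: int = 2000
    # enrichment
    ora_p_threshold: float = 0.01
    # generator noise overrides (None -> NoiseModel defaults)
    noise: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid_groups = {"PAC", "PAG", "PAI", "ADC", "ADG", "ADI"}
        for case, control in self.contrasts:
            if case not in valid_groups or control not in valid_groups:
                raise ConfigurationError(f"unknown group in contrast {case} vs {control}")
        if self.vip_percentile <= 0 or self.p_threshold <= 0 or self.ora_p_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        d["exclusions"] = [list(e) for e in self.exclusions]
        d["ppm_range"] = list(self.ppm_range)
        d["classifiers"] = list(self.classifiers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        if "exclusions" in d:
            d["exclusions"] = tuple(tuple(e) for e in d["exclusions"])
        if "ppm_range" in d:
            d["ppm_range"] = tuple(d["ppm_range"])
        if "classifiers" in d:
            d["classifiers"] = tuple(d["classifiers"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subseed(seed: int, name: str) -> int:
    """A named, reproducible sub-seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _design_from(config: PipelineConfig) -> CohortDesign:
    noise = NoiseModel(**config.noise) if config.noise else NoiseModel()
    return CohortDesign(seed=_subseed(config.seed, "cohort"), noise=noise)


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, **kw)


def _contrast_dir(rundir: Path, case: str, control: str) -> Path:
    d = rundir / f"{case}_vs_{control}"
    d.mkdir(exist_ok=True)
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, rundir: Path) -> None:
    design = _design_from(config)
    conc, clinical, manifest = generate_cohort(design)
    _write_csv(conc, rundir / "concentrations.csv", index_label="sample_id")
    _write_csv(clinical, rundir / "clinical.csv")
    (rundir / "manifest.json").write_text(json.dumps({
        "seed": manifest.seed,
        "planted": {f"{c} vs {k}": sorted(v) for (c, k), v in manifest.planted.items()},
        "groups": {label: int(n) for label, n in design.groups},
    }, indent=1))
    logger.info("simulate: %d samples, %d metabolites", *conc.shape)


def stage_preprocess(config: PipelineConfig, rundir: Path) -> None:
    conc = pd.read_csv(rundir / "concentrations.csv", index_col="sample_id")
    design = _design_from(config)
    spectra = synthesize_cohort_spectra(conc, design)
    spectra = [calibrate(s) for s in spectra]
    bins = bin_spectra(spectra, config.ppm_range, config.exclusions, config.bin_width)
    frame = bins.to_frame()
    _write_csv(frame, rundir / "bins.csv", index_label="sample_id")
    (rundir / "bins.meta.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "normalized": bins.normalized,
        "width": bins.width,
        "n_bins": int(bins.values.shape[1]),
        "excluded_regions": [list(e) for e in bins.excluded_regions],
    }, indent=1))
    amap = default_assignment_map(design.library)
    quant = quantify(spectra, amap, config.ppm_range, config.exclusions)
    _write_csv(quant.values, rundir / "quant.csv", index_label="sample_id")
    (rundir / "quant.meta.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "assignment_map": {m: [list(iv) for iv in ivs] for m, ivs in amap.items()},
    }, indent=1))
    logger.info("preprocess: %d bins, %d metabolites", bins.values.shape[1], len(amap))


def _load_tables(config: PipelineConfig, rundir: Path):
    from .spectra import BinMatrix

    clinical = pd.read_csv(rundir / "clinical.csv", index_col="sample_id")
    qmeta = json.loads((rundir / "quant.meta.json").read_text())
    quant = QuantTable(
        values=pd.read_csv(rundir / "quant.csv", index_col="sample_id"),
        assignment_map={m: [tuple(iv) for iv in ivs]
                        for m, ivs in qmeta["assignment_map"].items()},
    )
    bframe = pd.read_csv(rundir / "bins.csv", index_col="sample_id")
    bmeta = json.loads((rundir / "bins.meta.json").read_text())
    lows = np.array([float(c) for c in bframe.columns])
    edges = np.column_stack([lows, lows + bmeta["width"]])
    bins = BinMatrix(
        values=bframe.to_numpy(), bin_edges=edges,
        sample_ids=list(bframe.index), normalized=bmeta["normalized"],
        excluded_regions=tuple(tuple(e) for e in bmeta["excluded_regions"]),
        width=bmeta["width"],
    )
    return quant, bins, clinical


def stage_screen(config: PipelineConfig, rundir: Path) -> None:
    quant, bins, clinical = _load_tables(config, rundir)
    for case, control in config.contrasts:
        out = _contrast_dir(rundir, case, control)
        seed = _subseed(config.seed, f"screen:{case}:{control}")
        st = screen_contrast(
            quant, bins, clinical, case, control,
            vip_percentile=config.vip_percentile,
            vip_reference=config.vip_reference,
            p_threshold=config.p_threshold,
            n_orthogonal=config.n_orthogonal,
            cv_folds=config.cv_folds,
            seed=seed,
        )
        _write_csv(st.table, out / "screen.csv", index_label="metabolite")
        _write_csv(st.volcano_frame(), out / "volcano.csv", index=False)
        model = st.model
        (out / "model.json").write_text(json.dumps({
            "config_hash": config.config_hash(),
            "kind": model.kind,
            "R2X": model.r2x, "R2Y": model.r2y, "Q2": model.q2,
            "cv_anova_p": model.cv_anova_p,
            "n_orthogonal": model.n_orthogonal,
            "vip_cutoff": st.vip_cutoff,
            "r_threshold": st.r_threshold,
            "selected": st.selected,
        }, indent=1))
        # permutation validation on the same matrix
        mask = clinical["group"].isin([case, control]).to_numpy()
        X = pareto_scale(bins.values[mask])
        y = (clinical.loc[mask, "group"] == case).to_numpy().astype(int)
        rep = permutation_test(X, y, n_perm=config.n_permutations,
                               n_orthogonal=config.n_orthogonal,
                               cv_folds=config.cv_folds,
                               seed=_subseed(config.seed, f"perm:{case}:{control}"))
        (out / "permutation.json").write_text(json.dumps({
            "config_hash": config.config_hash(),
            "n_perm": rep.n_perm, "valid": rep.valid,
            "R2_original": rep.r2_original, "Q2_original": rep.q2_original,
            "R2_intercept": rep.r2_intercept, "Q2_intercept": rep.q2_intercept,
            "R2_permuted": rep.r2_values.tolist(),
            "Q2_permuted": rep.q2_values.tolist(),
            "correlations": rep.correlations.tolist(),
        }, indent=1))
        # correlation network between selected biomarkers and clinical indices
        if st.selected:
            sub = clinical.loc[mask, ["age", "sex"]]
            net = correlation_network(quant.values.loc[mask, st.selected], sub)
            _write_csv(net, out / "network.csv", index=False)
        logger.info("screen %s vs %s: %d selected, Q2=%.3f",
                    case, control, len(st.selected), model.q2)


def stage_diagnose(config: PipelineConfig, rundir: Path) -> None:
    quant, _, clinical = _load_tables(config, rundir)
    for case, control in config.contrasts:
        out = _contrast_dir(rundir, case, control)
        seed = _subseed(config.seed, f"diag:{case}:{control}")
        try:
            report = diagnose_contrast(
                quant.values, clinical, case, control,
                p_threshold=config.p_threshold,
                classifiers=config.classifiers, scheme=config.scheme,
                k=config.diag_folds, seed=seed, n_boot=config.n_boot,
            )
        except SSMetabError as exc:
            (out / "diagnostics.json").write_text(json.dumps({
                "config_hash": config.config_hash(), "error": str(exc)}))
            logger.warning("diagnose %s vs %s failed: %s", case, control, exc)
            continue
        payload = report.to_dict()
        payload["config_hash"] = config.config_hash()
        (out / "diagnostics.json").write_text(json.dumps(payload, indent=1))
        for name, rep in report.classifiers.items():
            _write_csv(pd.DataFrame({"fpr": rep.fpr, "tpr": rep.tpr}),
                       out / f"roc_{name}.csv", index=False)
        logger.info("diagnose %s vs %s: panel=%s", case, control, report.lasso_selected)


def stage_enrich(config: PipelineConfig, rundir: Path) -> None:
    catalog = default_catalog()
    for case, control in config.contrasts:
        out = _contrast_dir(rundir, case, control)
        model_path = out / "model.json"
        if not model_path.exists():
            continue
        selected = json.loads(model_path.read_text())["selected"]
        if not selected:
            logger.info("enrich %s vs %s: no biomarkers, skipped", case, control)
            continue
        query = set(selected) & catalog.universe
        if not query:
            logger.info("enrich %s vs %s: no annotatable biomarkers", case, control)
            continue
        result = ora(query, catalog, p_threshold=config.ora_p_threshold)
        _write_csv(result, out / "ora.csv", index=False)
        n_sig = int(result["significant"].sum())
        logger.info("enrich %s vs %s: %d significant pathways", case, control, n_sig)


_STAGE_FN = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "screen": stage_screen,
    "diagnose": stage_diagnose,
    "enrich": stage_enrich,
}


def run_pipeline(
    config: PipelineConfig,
    rundir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> Path:
    """Run the requested stages into ``rundir``; later stages read the files
    earlier stages wrote, so any prefix can be cached.  A mid-stage failure
    leaves prior outputs intact and records ``failure.log``."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(rundir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        for stage in stages:
            if stage not in _STAGE_FN:
                raise ConfigurationError(f"unknown stage: {stage}")
            logger.info("=== stage %s ===", stage)
            try:
                _STAGE_FN[stage](config, rundir)
            except Exception as exc:
                (rundir / "failure.log").write_text(f"stage {stage} failed: {exc}\n")
                raise
        _write_provenance(config, rundir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return rundir


def _write_provenance(config: PipelineConfig, rundir: Path) -> None:
    digests = {}
    for path in sorted(rundir.rglob("*")):
        if path.is_file() and path.name not in {"provenance.json", "pipeline.log"}:
            digests[str(path.relative_to(rundir))] = hashlib.sha256(
                path.read_bytes()).hexdigest()
    (rundir / "provenance.json").write_text(json.dumps({
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": digests,
    }, indent=1))
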