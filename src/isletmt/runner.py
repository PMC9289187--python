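"""End-to-end runs: simulate a plate, analyze stacks, summarize statistics.

Every run writes its resolved configuration and seed alongside the
results, plus a manifest of produced artifacts with content hashes, so
identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from isletmt.errors import ConfigError, IsletMTError
from isletmt.io import (
    read_functional_csv,
    read_layout_csv,
    read_stack_tiff,
    write_layout_csv,
    write_stack_tiff,
)
from isletmt.pipeline import (
    PipelineConfig,
    SegmentationConfig,
    SpheroidConfig,
    TruncationConfig,
    detect_spheroid,
    segment_nuclei,
    truncate_intensities,
)
from isletmt.quantify import (
    extract_records,
    quantifications_to_frame,
    quantify_mt,
    records_to_frame,
    spheroid_volume,
)
from isletmt.stats import (
    FOLD_STIMULATION,
    FUNCTIONAL_ENDPOINTS,
    PROLIFERATION_ENDPOINTS,
    summarize_endpoints,
)
from isletmt.synthetic import (
    DoseEffectModel,
    GeometryConfig,
    OpticsConfig,
    PhenotypeModel,
    default_layout,
    functional_to_frame,
    simulate_plate,
    truth_to_frame,
)

logger = logging.getLogger(__name__)

_STACK_NAME = re.compile(r"^(?P<well>[^_]+)_(?P<mt>mt\d+)\.tiff?$")


@dataclass
class RunConfig:
    """Full configuration of one simulate/analyze run."""

    seed: int = 0
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    phenotype: PhenotypeModel = field(default_factory=PhenotypeModel)
    dose_model: DoseEffectModel = field(default_factory=DoseEffectModel)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    control_dose: float = 0.0
    rout_q: float = 0.05
    fail_fast: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        try:
            for key, typ in (("optics", OpticsConfig), ("phenotype", PhenotypeModel),
                             ("dose_model", DoseEffectModel), ("geometry", GeometryConfig)):
                if key in d and isinstance(d[key], dict):
                    d[key] = typ(**d[key])
            if "pipeline" in d and isinstance(d["pipeline"], dict):
                p = dict(d["pipeline"])
                for key, typ in (("spheroid", SpheroidConfig),
                                 ("segmentation", SegmentationConfig),
                                 ("truncation", TruncationConfig)):
                    if key in p and isinstance(p[key], dict):
                        p[key] = typ(**p[key])
                d["pipeline"] = PipelineConfig(**p)
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, files: list[Path]) -> Path:
    manifest = {f.relative_to(outdir).as_posix(): _sha256(f) for f in sorted(files)}
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


# --------------------------------------------------------------------------
# simulate
# --------------------------------------------------------------------------

def run_simulate(config: RunConfig, outdir, layout: pd.DataFrame | None = None) -> Path:
    """Simulate a plate and write stacks, ground truth, functional records,
    layout, resolved config, and a hashed manifest. Returns the output dir."""
    outdir = Path(outdir)
    stacks_dir = outdir / "stacks"
    stacks_dir.mkdir(parents=True, exist_ok=True)
    if layout is None:
        layout = default_layout()

    mts = simulate_plate(layout, config.dose_model, config.phenotype,
                         config.optics, config.geometry, seed=config.seed,
                         render=True)
    written: list[Path] = []
    for mt in mts:
        path = stacks_dir / f"{mt.mt_id}.tif"
        write_stack_tiff(path, mt.stacks)
        written.append(path)

    truth_path = outdir / "ground_truth.csv"
    truth_to_frame(mts).to_csv(truth_path, index=False)
    functional_path = outdir / "functional.csv"
    functional_to_frame(mts, layout).to_csv(functional_path, index=False)
    layout_path = outdir / "layout.csv"
    write_layout_csv(layout, layout_path)
    config_path = outdir / "config.yaml"
    save_config(config, config_path)
    written += [truth_path, functional_path, layout_path, config_path]

    _write_manifest(outdir, written)
    logger.info("simulated %d microtissues into %s", len(mts), outdir)
    return outdir


# --------------------------------------------------------------------------
# analyze
# --------------------------------------------------------------------------

def analyze_stack(mt_id: str, stacks, config: RunConfig):
    """Run the 4-step pipeline on one stack; returns (records, quantification)."""
    pcfg = config.pipeline
    dapi, nkx, edu = stacks["dapi"], stacks["nkx6_1"], stacks["edu"]
    spheroid = detect_spheroid(dapi, pcfg.spheroid)
    nkx = truncate_intensities(nkx, pcfg.truncation.lower_pct,
                               pcfg.truncation.upper_pct, spheroid)
    nuclei = segment_nuclei(dapi, spheroid, pcfg.segmentation)
    records = extract_records(mt_id, nuclei, dapi, nkx, edu, spheroid,
                              pcfg.segmentation)
    quant = quantify_mt(records, spheroid_volume(spheroid), mt_id=mt_id)
    return records, quant


def run_analyze(config: RunConfig, stacks_dir, layout_path, outdir) -> Path:
    """Analyze every stack in a directory; per-stack failures are logged
    and skipped (unless ``fail_fast``), never aborting the plate."""
    stacks_dir = Path(stacks_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = read_layout_csv(layout_path)

    stack_files = sorted(p for p in stacks_dir.iterdir()
                         if p.suffix.lower() in (".tif", ".tiff"))
    if not stack_files:
        raise IsletMTError(f"no TIFF stacks found in {stacks_dir}")

    all_records, quants, failures = [], [], []
    for path in stack_files:
        mt_id = path.stem
        try:
            stacks = read_stack_tiff(path, channel_map=config.pipeline.channels)
            records, quant = analyze_stack(mt_id, stacks, config)
        except Exception as exc:
            if config.fail_fast:
                raise
            logger.error("stack %s failed: %s", path.name, exc)
            failures.append({"stack": path.name, "error": str(exc)})
            continue
        all_records.extend(records)
        quants.append(quant)
    if not quants:
        raise IsletMTError(f"all {len(stack_files)} stacks failed to analyze")

    per_nucleus = records_to_frame(all_records)
    per_mt = quantifications_to_frame(quants)

    # join well metadata via the mt_id -> well naming convention
    wells = per_mt["mt_id"].str.extract(_STACK_NAME.pattern.replace(r"\.tiff?", ""))
    per_mt = per_mt.assign(well=wells["well"])
    meta = layout[["well", "donor", "dose_uM", "duration_days", "treatment"]]
    per_mt = per_mt.merge(meta, on="well", how="left")
    if per_mt["dose_uM"].isna().any():
        unknown = sorted(per_mt.loc[per_mt["dose_uM"].isna(), "well"].unique())
        raise ConfigError(f"stacks reference wells absent from the layout: {unknown}")

    per_nucleus_path = outdir / "per_nucleus.csv"
    per_nucleus.to_csv(per_nucleus_path, index=False, na_rep="NA")
    per_mt_path = outdir / "per_mt.csv"
    per_mt.to_csv(per_mt_path, index=False, na_rep="NA")

    summary = summarize_endpoints(per_mt, sorted(PROLIFERATION_ENDPOINTS) + ["pct_beta"],
                                  control_dose=config.control_dose, q=config.rout_q)
    summary_path = outdir / "group_summary.csv"
    summary.to_csv(summary_path, index=False, na_rep="NA")

    config_path = outdir / "config.yaml"
    save_config(config, config_path)
    log_path = outdir / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"analyzed {len(quants)} / {len(stack_files)} stacks\n")
        for f in failures:
            fh.write(f"FAILED {f['stack']}: {f['error']}\n")

    _write_manifest(outdir, [per_nucleus_path, per_mt_path, summary_path, config_path])
    logger.info("analyzed %d stacks (%d failures) into %s",
                len(quants), len(failures), outdir)
    return outdir


def run_stats(functional_csv, outdir, per_mt_csv=None, control_dose: float = 0.0,
              q: float = 0.05) -> Path:
    """Dose-response summary tables for functional (and optionally imaging)
    endpoints, including derived fold-stimulation."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    functional = read_functional_csv(functional_csv)
    endpoints = [ep for ep in FUNCTIONAL_ENDPOINTS if ep in functional.columns]
    if {"basal_secretion", "stimulated_secretion"} <= set(functional.columns):
        endpoints.append(FOLD_STIMULATION)
    tables = [summarize_endpoints(functional, endpoints, control_dose=control_dose, q=q)]
    if per_mt_csv is not None:
        per_mt = pd.read_csv(per_mt_csv)
        imaging = [ep for ep in sorted(PROLIFERATION_ENDPOINTS) + ["pct_beta"]
                   if ep in per_mt.columns]
        tables.append(summarize_endpoints(per_mt, imaging,
                                          control_dose=control_dose, q=q))
    summary = pd.concat(tables, ignore_index=True)
    path = outdir / "endpoint_summary.csv"
    summary.to_csv(path, index=False, na_rep="NA")
    return outdir
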