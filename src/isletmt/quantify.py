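"""Per-microtissue metrics from label maps and marker scores.

Converts segmentation output into the per-microtissue summary a
screening analysis works with: total cell count (DAPI), β-cell count
(NKX6.1⁺), proliferating counts (EdU⁺), proliferating-β count by label
colocalization, derived percentages, mean NKX6.1 intensity, and spheroid
volume. Undefined percentages (zero denominators) are explicit missing
values, never zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from isletmt.grid import VoxelGrid
from isletmt.pipeline import (
    NucleusLabelMap,
    PipelineConfig,
    SegmentationConfig,
    SpheroidMask,
    score_markers,
)

logger = logging.getLogger(__name__)


@dataclass
class NucleusRecord:
    """One segmented nucleus with its marker scores."""

    mt_id: str
    label: int
    centroid: tuple[float, float, float]  # (x, y, z) µm, stack frame
    volume: float                          # µm³
    mean_dapi: float
    mean_nkx: float
    mean_edu: float
    is_beta: bool
    is_edu: bool

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError(f"nucleus volume must be > 0, got {self.volume}")


@dataclass
class MTQuantification:
    """Per-microtissue result. Percentages are ``nan`` when the
    denominator is zero (written as "NA" in CSV output)."""

    mt_id: str
    n_total: int
    n_beta: int
    n_edu: int
    n_edu_beta: int
    pct_beta: float
    pct_prolif_total: float
    pct_prolif_beta: float
    pct_prolif_nonbeta: float
    mean_nkx_intensity: float
    spheroid_volume: float

    def __post_init__(self) -> None:
        assert self.n_edu_beta <= min(self.n_beta, self.n_edu)
        assert self.n_beta <= self.n_total
        # conservation identities
        assert self.n_edu_beta + (self.n_edu - self.n_edu_beta) == self.n_edu
        assert self.n_beta + (self.n_total - self.n_beta) == self.n_total
        for p in (self.pct_beta, self.pct_prolif_total,
                  self.pct_prolif_beta, self.pct_prolif_nonbeta):
            assert math.isnan(p) or 0.0 <= p <= 100.0


def percentage(numerator: float, denominator: float) -> float:
    """``100 * numerator / denominator``; ``nan`` for a zero denominator.

    Accepts fractional inputs so it applies equally to group-mean counts
    (e.g. a mean of 2.7 EdU⁺ cells out of 1405 total is 0.2% total
    proliferation).
    """
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


def colocalize_labels(beta_ids: set[int], edu_ids: set[int]) -> set[int]:
    """Proliferating-β nuclei: labels carrying both NKX6.1 and EdU.

    Both sets must be drawn from the same label map; the result is
    exactly their intersection.
    """
    return set(beta_ids) & set(edu_ids)


def extract_records(
    mt_id: str,
    nuclei: NucleusLabelMap,
    dapi: VoxelGrid,
    nkx: VoxelGrid,
    edu: VoxelGrid,
    spheroid: SpheroidMask,
    config: SegmentationConfig | None = None,
) -> list[NucleusRecord]:
    """Score both marker channels on a label map and build nucleus records.

    Centroids are intensity-free label centroids in the stack's physical
    frame, reported as (x, y, z) µm; volumes are voxel counts times the
    physical voxel volume.
    """
    config = config or SegmentationConfig()
    if nuclei.n_labels == 0:
        return []
    index = np.arange(1, nuclei.n_labels + 1)
    voxvol = float(np.prod(nuclei.voxel_size))
    counts = ndimage.sum_labels(np.ones_like(nuclei.labels), nuclei.labels, index=index)
    centroids_zyx = ndimage.center_of_mass(
        np.ones_like(nuclei.labels), nuclei.labels, index=index)
    dapi_means = ndimage.mean(dapi.data, labels=nuclei.labels, index=index)
    nkx_scores = score_markers(nkx, nuclei, spheroid, config)
    edu_scores = score_markers(edu, nuclei, spheroid, config)

    records = []
    for i, lbl in enumerate(index):
        cz, cy, cx = centroids_zyx[i]
        dz, dy, dx = nuclei.voxel_size
        records.append(NucleusRecord(
            mt_id=mt_id, label=int(lbl),
            centroid=((cx + 0.5) * dx, (cy + 0.5) * dy, (cz + 0.5) * dz),
            volume=float(counts[i]) * voxvol,
            mean_dapi=float(dapi_means[i]),
            mean_nkx=nkx_scores[i][1],
            mean_edu=edu_scores[i][1],
            is_beta=nkx_scores[i][2],
            is_edu=edu_scores[i][2],
        ))
    return records


def quantify_mt(records: list[NucleusRecord], spheroid_volume: float,
                mt_id: str | None = None,
                nkx_mean_over: str = "beta") -> MTQuantification:
    """Summarize one microtissue's nucleus records.

    ``pct_prolif_beta = 100 * n_edu_beta / n_beta`` and
    ``pct_prolif_nonbeta = 100 * (n_edu - n_edu_beta) / (n_total - n_beta)``;
    zero denominators yield missing values (``nan``) with a logged
    warning. ``mean_nkx_intensity`` averages over β-classified nuclei by
    default (``nkx_mean_over="beta"``) or over all nuclei
    (``nkx_mean_over="all"``). An empty record list gives all-zero counts
    with every percentage missing.
    """
    if nkx_mean_over not in ("beta", "all"):
        raise ValueError(f"nkx_mean_over must be 'beta' or 'all', got {nkx_mean_over!r}")
    if mt_id is None:
        mt_id = records[0].mt_id if records else ""

    n_total = len(records)
    n_beta = sum(r.is_beta for r in records)
    n_edu = sum(r.is_edu for r in records)
    n_edu_beta = sum(r.is_beta and r.is_edu for r in records)

    def pct(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s: %s undefined (zero denominator)", mt_id, name)
        return percentage(num, den)

    nkx_pool = [r.mean_nkx for r in records
                if nkx_mean_over == "all" or r.is_beta]
    return MTQuantification(
        mt_id=mt_id,
        n_total=n_total, n_beta=n_beta, n_edu=n_edu, n_edu_beta=n_edu_beta,
        pct_beta=pct(n_beta, n_total, "pct_beta"),
        pct_prolif_total=pct(n_edu, n_total, "pct_prolif_total"),
        pct_prolif_beta=pct(n_edu_beta, n_beta, "pct_prolif_beta"),
        pct_prolif_nonbeta=pct(n_edu - n_edu_beta, n_total - n_beta,
                               "pct_prolif_nonbeta"),
        mean_nkx_intensity=float(np.mean(nkx_pool)) if nkx_pool else float("nan"),
        spheroid_volume=float(spheroid_volume),
    )


def spheroid_volume(mask: SpheroidMask,
                    voxel_size: tuple[float, float, float] | None = None) -> float:
    """Foreground voxel count times the physical voxel volume, in µm³."""
    vs = voxel_size if voxel_size is not None else mask.voxel_size
    return float(np.count_nonzero(mask.mask)) * float(np.prod(vs))


def volume_change(volumes: list[tuple[float, float]]) -> list[float]:
    """Relative volume change between consecutive timepoints.

    ``volumes`` is a time-ordered list of ``(timepoint, volume µm³)``;
    returns ``(V_t2 - V_t1) / V_t1`` for each consecutive pair.
    """
    if len(volumes) < 2:
        raise ValueError("need at least 2 timepoints")
    vols = [v for _, v in volumes]
    if any(v <= 0 for v in vols):
        raise ValueError("all volumes must be > 0")
    return [(v2 - v1) / v1 for v1, v2 in zip(vols[:-1], vols[1:])]


# --------------------------------------------------------------------------
# tabulation
# --------------------------------------------------------------------------

MT_CSV_COLUMNS = [
    "mt_id", "n_total", "n_beta", "n_edu", "n_edu_beta",
    "pct_beta", "pct_prolif_total", "pct_prolif_beta", "pct_prolif_nonbeta",
    "mean_nkx_intensity", "spheroid_volume",
]


def quantifications_to_frame(quants: list[MTQuantification]) -> pd.DataFrame:
    """One row per microtissue; missing percentages stay ``nan`` (written
    as "NA" by :func:`write_mt_csv`). Percentages are reported at full
    precision here; round only at presentation time."""
    return pd.DataFrame([{c: getattr(q, c) for c in MT_CSV_COLUMNS}
                         for q in quants], columns=MT_CSV_COLUMNS)


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mt_id": r.mt_id, "label": r.label,
        "x_um": r.centroid[0], "y_um": r.centroid[1], "z_um": r.centroid[2],
        "volume_um3": r.volume,
        "mean_dapi": r.mean_dapi, "mean_nkx": r.mean_nkx, "mean_edu": r.mean_edu,
        "is_beta": r.is_beta, "is_edu": r.is_edu,
    } for r in records])


def write_mt_csv(quants: list[MTQuantification], path) -> None:
    quantifications_to_frame(quants).to_csv(path, index=False, na_rep="NA")
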