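"""Synthetic islet-microtissue confocal stacks with per-nucleus ground truth.

The simulator emulates the statistical structure the analysis pipeline
assumes: a roughly spherical microtissue of densely but non-overlappingly
packed nuclei, a β-cell fraction of 40–65% (NKX6.1⁺), near-zero baseline
proliferation (EdU⁺), dose-dependent proliferation rising to ~6% of all
cells at saturating doses with non-β proliferation 5–10× that of β-cells,
a broad lognormal NKX6.1 intensity distribution with attenuated NKX6.1 in
proliferating β-cells, anisotropic confocal sampling (3 µm Z-step), and
Hill-type dose effects on the insulin-secretion endpoints.

The forward imaging model renders each channel as a sum of per-nucleus
indicator volumes scaled by amplitude, convolved with an anisotropic
Gaussian point-spread function, plus a constant background, followed by
Poisson photon resampling and additive Gaussian read noise.

The 4-day EdU labeling window is collapsed to a single cumulative
Bernoulli "proliferated during window" event per cell; no cell-cycle
dynamics are modeled.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from isletmt.errors import ConfigError, PackingError, StackBoundsError
from isletmt.grid import VoxelGrid

CHANNELS = ("dapi", "nkx6_1", "edu")

#: Fraction of the spheroid volume that nuclei may occupy before a packing
#: request is rejected as infeasible outright.
MAX_PACKING_FRACTION = 0.60

#: Rejection-sampling attempts per nucleus before packing fails.
MAX_ATTEMPTS_PER_CELL = 10_000


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------

@dataclass
class OpticsConfig:
    """Imaging geometry and noise model.

    ``voxel_z`` defaults to the 3 µm confocal Z-step; the XY pixel size is
    instrument-dependent and defaults to 0.5 µm/pixel. ``photon_scale`` is
    the Poisson gain: expected photon count per voxel is
    ``intensity * photon_scale`` (``math.inf`` disables shot noise).
    """

    voxel_xy: float = 0.5         # µm / pixel
    voxel_z: float = 3.0          # µm / plane
    psf_sigma_xy: float = 0.6     # µm
    psf_sigma_z: float = 1.8      # µm
    background_level: float = 8.0     # intensity a.u.
    noise_gaussian_sd: float = 2.0    # intensity a.u. (read noise)
    photon_scale: float = 1.0         # dimensionless Poisson gain
    bit_depth: int = 16

    def __post_init__(self) -> None:
        for name in ("voxel_xy", "voxel_z", "psf_sigma_xy", "psf_sigma_z"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.voxel_z < self.voxel_xy:
            raise ConfigError("voxel_z must be >= voxel_xy (anisotropic confocal sampling)")
        if self.bit_depth not in (8, 16):
            raise ConfigError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.background_level < 0 or self.noise_gaussian_sd < 0:
            raise ConfigError("background_level and noise_gaussian_sd must be >= 0")
        if self.photon_scale <= 0:
            raise ConfigError("photon_scale must be > 0 (math.inf disables shot noise)")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel extent ``(dz, dy, dx)`` in µm."""
        return (self.voxel_z, self.voxel_xy, self.voxel_xy)

    @property
    def max_intensity(self) -> float:
        return float(2 ** self.bit_depth - 1)


@dataclass
class PhenotypeModel:
    """Per-cell identity, proliferation, and staining-amplitude model.

    Proliferation rates are cumulative probabilities over the 4-day EdU
    labeling window. ``nkx_prolif_attenuation`` scales the NKX6.1
    amplitude of proliferating β-cells (< 1 encodes the reduced NKX6.1
    expression observed in EdU/NKX6.1 double-positive cells);
    ``nkx_bleedthrough_nonbeta`` is the constant non-β NKX6.1 floor.
    """

    beta_fraction: float = 0.55
    prolif_rate_beta: float = 0.002
    prolif_rate_nonbeta: float = 0.002
    nkx_mean_beta: float = 120.0      # intensity a.u.
    nkx_cv_beta: float = 0.40
    nkx_prolif_attenuation: float = 0.6
    nkx_bleedthrough_nonbeta: float = 10.0
    edu_amplitude: float = 150.0
    dapi_amplitude: float = 100.0
    dapi_cv: float = 0.10
    edu_cv: float = 0.15
    #: diffuse DAPI signal inside the microtissue but outside nuclei
    #: (cytoplasmic background, scatter, out-of-focus haze in cleared
    #: tissue); this is what makes whole-spheroid detection possible.
    dapi_interstitial: float = 20.0

    def __post_init__(self) -> None:
        for name in ("beta_fraction", "prolif_rate_beta", "prolif_rate_nonbeta"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.nkx_prolif_attenuation <= 1.0:
            raise ConfigError("nkx_prolif_attenuation must be in (0, 1]")
        for name in ("nkx_mean_beta", "edu_amplitude", "dapi_amplitude"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("nkx_cv_beta", "nkx_bleedthrough_nonbeta", "dapi_cv", "edu_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class GroundTruthCell:
    """Simulator-side truth for one nucleus (verification record)."""

    id: int
    center: tuple[float, float, float]  # (x, y, z) µm, spheroid-centered frame
    radius: float                       # µm
    is_beta: bool
    is_proliferating: bool
    channel_amplitudes: dict[str, float] = field(default_factory=dict)


@dataclass
class DoseEffectModel:
    """Hill-type dose effects on proliferation and functional endpoints.

    Proliferation probabilities follow
    ``baseline + (emax - baseline) * d**h / (ec50**h + d**h)`` where the
    baselines come from the :class:`PhenotypeModel`. Secretion endpoints
    are scaled multiplicatively: stimulated and chronic secretion rise
    along the same Hill curve, basal secretion rises linearly with dose,
    and insulin content is depleted exponentially with dose. ATP and
    caspase are dose-independent (the compound does not measurably affect
    viability or apoptosis in this model). Per-microtissue endpoint values
    are drawn lognormally around the dose-dependent means with
    coefficient of variation ``endpoint_cv``.
    """

    emax_prolif_beta: float = 0.015
    emax_prolif_nonbeta: float = 0.115
    ec50: float = 1.2                 # µM
    hill: float = 2.5
    basal_secretion_slope: float = 0.20       # fractional increase per µM
    stim_secretion_effect: float = 2.2        # max fractional increase (Hill)
    chronic_secretion_effect: float = 1.5     # max fractional increase (Hill)
    content_depletion_slope: float = 0.05     # exponential decay per µM
    baseline_basal: float = 0.5       # ng/MT per 2 h
    baseline_stimulated: float = 2.5  # ng/MT per 2 h
    baseline_chronic: float = 1.5     # ng/MT/day
    baseline_content: float = 25.0    # ng/MT
    baseline_atp: float = 20.0        # pmol/MT
    baseline_caspase: float = 1000.0  # a.u.
    endpoint_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ConfigError("ec50 must be > 0")
        if self.hill <= 0:
            raise ConfigError("hill must be > 0")
        for name in ("emax_prolif_beta", "emax_prolif_nonbeta"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in (
            "baseline_basal", "baseline_stimulated", "baseline_chronic",
            "baseline_content", "baseline_atp", "baseline_caspase",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    def hill_fraction(self, dose: float) -> float:
        """Fractional occupancy of the Hill curve at ``dose`` µM, in [0, 1)."""
        if dose < 0:
            raise ValueError(f"dose must be >= 0, got {dose}")
        if dose == 0:
            return 0.0
        dh = dose ** self.hill
        return dh / (self.ec50 ** self.hill + dh)

    def prolif_probability(self, dose: float, baseline: float, emax: float) -> float:
        return baseline + (emax - baseline) * self.hill_fraction(dose)

    def prolif_rates(self, dose: float, phenotype: PhenotypeModel) -> tuple[float, float]:
        """(β, non-β) proliferation probabilities at ``dose``."""
        return (
            self.prolif_probability(dose, phenotype.prolif_rate_beta, self.emax_prolif_beta),
            self.prolif_probability(dose, phenotype.prolif_rate_nonbeta, self.emax_prolif_nonbeta),
        )

    def expected_total_prolif(self, dose: float, phenotype: PhenotypeModel) -> float:
        """Expected EdU⁺ fraction of all cells at ``dose`` (generative truth)."""
        p_b, p_nb = self.prolif_rates(dose, phenotype)
        f = phenotype.beta_fraction
        return f * p_b + (1.0 - f) * p_nb

    def endpoint_means(self, dose: float) -> dict[str, float]:
        """Dose-dependent mean of each functional endpoint."""
        h = self.hill_fraction(dose)
        return {
            "basal_secretion": self.baseline_basal * (1.0 + self.basal_secretion_slope * dose),
            "stimulated_secretion": self.baseline_stimulated * (1.0 + self.stim_secretion_effect * h),
            "chronic_secretion": self.baseline_chronic * (1.0 + self.chronic_secretion_effect * h),
            "insulin_content": self.baseline_content * math.exp(-self.content_depletion_slope * dose),
            "atp_content": self.baseline_atp,
            "caspase_lum": self.baseline_caspase,
        }


@dataclass
class GeometryConfig:
    """Spheroid and nucleus geometry. Test-scale defaults (40 µm radius,
    ~200 nuclei) keep full-pipeline runs to seconds per stack; see
    :func:`paper_scale_geometry` for the 150 µm-diameter, ~1700-cell
    preset matching a 1-IEQ microtissue."""

    n_cells: int = 200
    spheroid_radius: float = 40.0       # µm
    nucleus_radius_mean: float = 3.0    # µm
    nucleus_radius_cv: float = 0.15
    packing_tolerance: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        for name in ("spheroid_radius", "nucleus_radius_mean", "packing_tolerance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.nucleus_radius_cv < 0:
            raise ConfigError("nucleus_radius_cv must be >= 0")


def paper_scale_geometry() -> GeometryConfig:
    """~1700 nuclei in a 150 µm-diameter spheroid (1 islet equivalent)."""
    return GeometryConfig(n_cells=1700, spheroid_radius=75.0)


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _draw_lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    if cv == 0:
        return mean if size is None else np.full(size, mean)
    mu, sigma = _lognormal_params(mean, cv)
    return rng.lognormal(mu, sigma, size=size)


class _SpatialHash:
    """Uniform-grid neighbor lookup for sphere-overlap rejection tests."""

    def __init__(self, cell_size: float):
        self.cell_size = cell_size
        self._cells: dict[tuple[int, int, int], list[tuple[np.ndarray, float]]] = {}

    def _key(self, p: np.ndarray) -> tuple[int, int, int]:
        return tuple(int(math.floor(c / self.cell_size)) for c in p)

    def overlaps(self, center: np.ndarray, radius: float, tol: float) -> bool:
        kx, ky, kz = self._key(center)
        for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
            for other_c, other_r in self._cells.get((kx + dx, ky + dy, kz + dz), ()):
                min_dist = (radius + other_r) * tol
                if np.dot(center - other_c, center - other_c) < min_dist * min_dist:
                    return True
        return False

    def insert(self, center: np.ndarray, radius: float) -> None:
        self._cells.setdefault(self._key(center), []).append((center, radius))


def generate_spheroid_geometry(
    n_cells: int,
    spheroid_radius: float,
    nucleus_radius_mean: float = 3.0,
    nucleus_radius_cv: float = 0.15,
    seed: int = 0,
    packing_tolerance: float = 1.0,
    max_attempts: int = MAX_ATTEMPTS_PER_CELL,
) -> list[tuple[tuple[float, float, float], float]]:
    """Place ``n_cells`` non-overlapping nuclear spheres inside a spheroid.

    Centers are in a spheroid-centered frame (origin at the spheroid
    center), units µm, ordered as drawn (insertion order breaks ties).
    Placement is rejection sampling against a spatial hash; two nuclei
    are accepted when their center distance is at least
    ``packing_tolerance`` times the sum of their radii.

    Raises
    ------
    PackingError
        If the requested nuclear volume exceeds 60% of the spheroid
        volume, or a nucleus cannot be placed within ``max_attempts``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells == 0:
        return []
    if spheroid_radius <= 2.0 * nucleus_radius_mean:
        raise ValueError(
            f"spheroid_radius ({spheroid_radius}) must exceed twice the mean "
            f"nucleus radius ({nucleus_radius_mean})"
        )

    rng = np.random.default_rng(seed)
    radii = np.asarray(_draw_lognormal(rng, nucleus_radius_mean, nucleus_radius_cv, size=n_cells))

    total_nuclear = float(np.sum(4.0 / 3.0 * np.pi * radii ** 3))
    spheroid_vol = 4.0 / 3.0 * np.pi * spheroid_radius ** 3
    if total_nuclear > MAX_PACKING_FRACTION * spheroid_vol:
        raise PackingError(
            n_cells, 0,
            f"infeasible packing: requested nuclear volume {total_nuclear:.0f} µm³ "
            f"exceeds {MAX_PACKING_FRACTION:.0%} of the spheroid volume "
            f"({spheroid_vol:.0f} µm³)",
        )

    hash_cell = 2.0 * float(np.max(radii))
    grid = _SpatialHash(hash_cell)
    placed: list[tuple[tuple[float, float, float], float]] = []
    for i in range(n_cells):
        r = float(radii[i])
        max_center = spheroid_radius - r
        if max_center <= 0:
            raise PackingError(n_cells, len(placed),
                               f"nucleus radius {r:.2f} µm does not fit inside the spheroid")
        for _ in range(max_attempts):
            # uniform point in the ball of radius max_center
            p = rng.normal(size=3)
            p /= np.linalg.norm(p)
            p *= max_center * rng.uniform() ** (1.0 / 3.0)
            if not grid.overlaps(p, r, packing_tolerance):
                grid.insert(p, r)
                placed.append((tuple(float(c) for c in p), r))
                break
        else:
            raise PackingError(n_cells, len(placed))
    return placed


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------

def assign_phenotypes(
    cells: list[tuple[tuple[float, float, float], float]],
    model: PhenotypeModel,
    seed: int = 0,
) -> list[GroundTruthCell]:
    """Draw identity, proliferation status, and staining amplitudes per cell.

    Each cell is independently β with probability ``beta_fraction`` and
    proliferating with the class-specific rate. NKX6.1 amplitudes of
    β-cells are lognormal (mean ``nkx_mean_beta``, CV ``nkx_cv_beta``),
    attenuated by ``nkx_prolif_attenuation`` when the cell proliferates;
    non-β cells carry the constant bleed-through floor. EdU amplitude is
    nonzero only in proliferating cells.
    """
    rng = np.random.default_rng(seed)
    n = len(cells)
    is_beta = rng.uniform(size=n) < model.beta_fraction
    rates = np.where(is_beta, model.prolif_rate_beta, model.prolif_rate_nonbeta)
    is_prolif = rng.uniform(size=n) < rates

    dapi = np.asarray(_draw_lognormal(rng, model.dapi_amplitude, model.dapi_cv, size=n))
    nkx = np.asarray(_draw_lognormal(rng, model.nkx_mean_beta, model.nkx_cv_beta, size=n))
    nkx = np.where(is_prolif, nkx * model.nkx_prolif_attenuation, nkx)
    nkx = np.where(is_beta, nkx, model.nkx_bleedthrough_nonbeta)
    edu = np.asarray(_draw_lognormal(rng, model.edu_amplitude, model.edu_cv, size=n))
    edu = np.where(is_prolif, edu, 0.0)

    return [
        GroundTruthCell(
            id=i, center=center, radius=radius,
            is_beta=bool(is_beta[i]), is_proliferating=bool(is_prolif[i]),
            channel_amplitudes={"dapi": float(dapi[i]), "nkx6_1": float(nkx[i]),
                                "edu": float(edu[i])},
        )
        for i, (center, radius) in enumerate(cells)
    ]


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def default_stack_shape(spheroid_radius: float, optics: OpticsConfig,
                        margin_um: float = 4.0) -> tuple[int, int, int]:
    """Smallest stack (nz, ny, nx) containing the spheroid plus a margin."""
    extent = 2.0 * (spheroid_radius + margin_um)
    nz = int(math.ceil(extent / optics.voxel_z))
    nxy = int(math.ceil(extent / optics.voxel_xy))
    return (nz, nxy, nxy)


def render_stack(
    cells: list[GroundTruthCell],
    optics: OpticsConfig,
    stack_shape: tuple[int, int, int],
    seed: int | None = 0,
    channels: tuple[str, ...] = CHANNELS,
    spheroid: tuple[float, dict[str, float]] | None = None,
) -> dict[str, VoxelGrid]:
    """Render one multi-channel confocal stack from ground-truth cells.

    Cell centers (spheroid frame, origin at the spheroid center) are
    placed at the physical center of the stack. Per channel the expected
    image is the amplitude-weighted sum of nuclear indicator volumes
    convolved with the anisotropic Gaussian PSF plus the background;
    noise is Poisson photon resampling at ``photon_scale`` followed by
    additive Gaussian read noise, clipped to the bit depth. Pass
    ``photon_scale=math.inf`` and ``noise_gaussian_sd=0`` for a
    noise-free render (then ``seed`` may be ``None``).

    ``spheroid`` optionally adds a diffuse tissue component: a
    ``(radius_um, {channel: amplitude})`` ball indicator centered with
    the cells, blurred by the same PSF, modeling interstitial signal in
    cleared tissue. With ``spheroid=None`` the expected image is the
    nuclear sum plus background only.

    Raises
    ------
    StackBoundsError
        If any nuclear sphere extends beyond the stack, listing ids.
    """
    nz, ny, nx = stack_shape
    voxel = np.array(optics.voxel_size)           # (dz, dy, dx)
    extent = np.array([nz, ny, nx]) * voxel       # physical (z, y, x)
    offset = extent / 2.0                         # spheroid center in stack frame

    # bounds check (centers are (x, y, z) in the truth records)
    offending = []
    for cell in cells:
        czyx = np.array([cell.center[2], cell.center[1], cell.center[0]]) + offset
        if np.any(czyx - cell.radius < 0) or np.any(czyx + cell.radius > extent):
            offending.append(cell.id)
    if offending:
        raise StackBoundsError(offending)

    base = {ch: np.zeros(stack_shape, dtype=np.float64) for ch in channels}
    zc = (np.arange(nz) + 0.5) * voxel[0]
    yc = (np.arange(ny) + 0.5) * voxel[1]
    xc = (np.arange(nx) + 0.5) * voxel[2]

    for cell in cells:
        cz = cell.center[2] + offset[0]
        cy = cell.center[1] + offset[1]
        cx = cell.center[0] + offset[2]
        r = cell.radius
        # bounding box in voxel indices
        z0, z1 = np.searchsorted(zc, [cz - r, cz + r])
        y0, y1 = np.searchsorted(yc, [cy - r, cy + r])
        x0, x1 = np.searchsorted(xc, [cx - r, cx + r])
        z1, y1, x1 = min(z1 + 1, nz), min(y1 + 1, ny), min(x1 + 1, nx)
        dz = zc[z0:z1] - cz
        dy = yc[y0:y1] - cy
        dx = xc[x0:x1] - cx
        inside = (dz[:, None, None] ** 2 + dy[None, :, None] ** 2
                  + dx[None, None, :] ** 2) <= r * r
        for ch in channels:
            amp = cell.channel_amplitudes.get(ch, 0.0)
            if amp:
                base[ch][z0:z1, y0:y1, x0:x1] += amp * inside

    if spheroid is not None:
        s_radius, s_amps = spheroid
        ball = ((zc[:, None, None] - offset[0]) ** 2
                + (yc[None, :, None] - offset[1]) ** 2
                + (xc[None, None, :] - offset[2]) ** 2) <= s_radius ** 2
        for ch in channels:
            amp = s_amps.get(ch, 0.0)
            if amp:
                base[ch] += amp * ball

    sigma_vox = (optics.psf_sigma_z / voxel[0],
                 optics.psf_sigma_xy / voxel[1],
                 optics.psf_sigma_xy / voxel[2])
    noisy = math.isfinite(optics.photon_scale) or optics.noise_gaussian_sd > 0
    rng = np.random.default_rng(seed) if noisy else None

    out: dict[str, VoxelGrid] = {}
    for ch in channels:
        img = ndimage.gaussian_filter(base[ch], sigma=sigma_vox)
        img += optics.background_level
        if math.isfinite(optics.photon_scale):
            img = rng.poisson(img * optics.photon_scale).astype(np.float64) / optics.photon_scale
        if optics.noise_gaussian_sd > 0:
            img += rng.normal(0.0, optics.noise_gaussian_sd, size=img.shape)
        np.clip(img, 0.0, optics.max_intensity, out=img)
        out[ch] = VoxelGrid(data=img, voxel_size=tuple(voxel), channel_name=ch)
    return out


# --------------------------------------------------------------------------
# plate simulation
# --------------------------------------------------------------------------

LAYOUT_COLUMNS = ("well", "donor", "dose_uM", "duration_days", "treatment", "n_mts")


def default_layout(doses=(0.0, 1.0, 3.3, 5.0, 10.0), n_mts: int = 6,
                   donor: str = "donor1", duration_days: int = 4) -> pd.DataFrame:
    """One-well-per-dose plate layout at the study's dose ladder (0–10 µM)."""
    rows = [
        {"well": f"{chr(ord('A') + i)}01", "donor": donor, "dose_uM": float(d),
         "duration_days": duration_days,
         "treatment": "vehicle" if d == 0 else "compound", "n_mts": n_mts}
        for i, d in enumerate(doses)
    ]
    return pd.DataFrame(rows, columns=list(LAYOUT_COLUMNS))


def validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise ConfigError(f"plate layout missing columns: {missing}")
    if layout["well"].duplicated().any():
        dups = layout.loc[layout["well"].duplicated(), "well"].tolist()
        raise ConfigError(f"duplicate wells in layout: {dups}")
    if (layout["dose_uM"] < 0).any():
        raise ConfigError("doses must be >= 0")
    if (layout["n_mts"] < 1).any():
        raise ConfigError("n_mts must be >= 1 for every well")
    return layout


@dataclass
class SimulatedMT:
    """One simulated microtissue: stacks, truth, and functional readouts."""

    mt_id: str
    well: str
    dose: float
    truth: list[GroundTruthCell]
    stacks: dict[str, VoxelGrid] | None
    functional: dict[str, float]


def simulate_functional_record(dose_model: DoseEffectModel, dose: float,
                               rng: np.random.Generator) -> dict[str, float]:
    """Draw one microtissue's functional endpoints (lognormal around the
    dose-dependent means)."""
    means = dose_model.endpoint_means(dose)
    return {k: float(_draw_lognormal(rng, m, dose_model.endpoint_cv))
            for k, m in means.items()}


def simulate_plate(
    layout: pd.DataFrame,
    dose_model: DoseEffectModel | None = None,
    phenotype: PhenotypeModel | None = None,
    optics: OpticsConfig | None = None,
    geometry: GeometryConfig | None = None,
    seed: int = 0,
    render: bool = True,
) -> list[SimulatedMT]:
    """Simulate every microtissue on a plate: geometry, phenotypes, stacks,
    and functional endpoints, fully reproducible given ``seed``.

    Proliferation probabilities per well follow the Hill dose-response of
    ``dose_model`` on top of the phenotype baselines; functional endpoints
    are drawn lognormally around dose-dependent means. With
    ``render=False`` only ground truth and functional records are
    produced (no imaging), which is orders of magnitude faster and is
    sufficient for truth-level statistical studies.
    """
    dose_model = dose_model or DoseEffectModel()
    phenotype = phenotype or PhenotypeModel()
    optics = optics or OpticsConfig()
    geometry = geometry or GeometryConfig()
    layout = validate_layout(layout)

    stack_shape = default_stack_shape(geometry.spheroid_radius, optics)
    root = np.random.SeedSequence(seed)
    out: list[SimulatedMT] = []
    for well_index, (_, row) in enumerate(layout.iterrows()):
        dose = float(row["dose_uM"])
        p_beta, p_nonbeta = dose_model.prolif_rates(dose, phenotype)
        well_model = replace(phenotype, prolif_rate_beta=p_beta,
                             prolif_rate_nonbeta=p_nonbeta)
        for k in range(int(row["n_mts"])):
            mt_seeds = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(well_index, k)
            ).generate_state(4)
            geom = generate_spheroid_geometry(
                geometry.n_cells, geometry.spheroid_radius,
                geometry.nucleus_radius_mean, geometry.nucleus_radius_cv,
                seed=int(mt_seeds[0]), packing_tolerance=geometry.packing_tolerance,
            )
            truth = assign_phenotypes(geom, well_model, seed=int(mt_seeds[1]))
            interstitial = (geometry.spheroid_radius,
                            {"dapi": phenotype.dapi_interstitial})
            stacks = (render_stack(truth, optics, stack_shape, seed=int(mt_seeds[2]),
                                   spheroid=interstitial)
                      if render else None)
            functional = simulate_functional_record(
                dose_model, dose, np.random.default_rng(int(mt_seeds[3])))
            out.append(SimulatedMT(
                mt_id=f"{row['well']}_mt{k:02d}", well=str(row["well"]),
                dose=dose, truth=truth, stacks=stacks, functional=functional,
            ))
    return out


def truth_to_frame(mts: list[SimulatedMT]) -> pd.DataFrame:
    """Flatten ground truth to one row per nucleus."""
    rows = []
    for mt in mts:
        for c in mt.truth:
            rows.append({
                "mt_id": mt.mt_id, "id": c.id,
                "x_um": c.center[0], "y_um": c.center[1], "z_um": c.center[2],
                "radius_um": c.radius,
                "is_beta": c.is_beta, "is_proliferating": c.is_proliferating,
            })
    return pd.DataFrame(rows)


def functional_to_frame(mts: list[SimulatedMT], layout: pd.DataFrame) -> pd.DataFrame:
    """Per-microtissue functional records joined with well metadata."""
    meta = layout.set_index("well")
    rows = []
    for mt in mts:
        m = meta.loc[mt.well]
        rows.append({
            "mt_id": mt.mt_id, "well": mt.well, "donor": m["donor"],
            "dose_uM": mt.dose, "duration_days": int(m["duration_days"]),
            **mt.functional,
        })
    return pd.DataFrame(rows)
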