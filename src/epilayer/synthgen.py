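"""Synthetic, class-labeled inputs with known ground truth.

Emulates the features of real confocal data that drive the classifier:
nuclear z distributions (narrow Gaussian for organized sheets; wide or
overlapping-bimodal for disorganized ones; separated-bimodal for a layer
with apically attached cells; plus three "extreme" organized
configurations — a double layer, a clump of cells on an organized layer,
and a pyramid of cells on an organized layer), actin z templates
(basally-weighted Immature, monopeaked Intermediate, shouldered Mature
with an apical band), lateral actin on Voronoi cell boundaries, debris
objects for the volume filter, and movies decorrelating at a known
exponential rate.  Everything is deterministic per seed.

No attempt is made at photorealism (no PSF, no shot noise): the templates
only need to drive the decision features, and that limitation is the
point — recovery tests certify the rules, not microscope physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import ImageStack, NucleusRecord, NucleiTable
from .dynamics import Movie

ORGANIZED_CLASSES = ("Immature", "Intermediate", "Mature")
EXTREME_CLASSES = ("extreme_double", "extreme_clump", "extreme_pyramid")
ALL_CLASSES = ORGANIZED_CLASSES + ("Disorganized",) + EXTREME_CLASSES


@dataclass
class LayerScenario:
    """Ground-truth description of one synthetic field."""

    class_label: str
    density_kcells_per_mm2: float
    layer_height_um: float
    nuclear_sigma_um: float = 1.0
    field_um: tuple[float, float] = (300.0, 300.0)
    apical_fraction: float = 0.0
    debris_fraction: float = 0.0
    noise_sd: float = 0.0
    bottom_um: float = 1.0
    voxel_xy_um: float = 0.3
    voxel_z_um: float = 0.23
    mean_volume_um3: float = 500.0
    volume_sd_um3: float = 50.0
    debris_volume_um3: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ALL_CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}")
        for name in ("apical_fraction", "debris_fraction"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.density_kcells_per_mm2 <= 0:
            raise ValueError("density must be positive")

    @property
    def top_um(self) -> float:
        return self.bottom_um + self.layer_height_um

    def n_nuclei(self) -> int:
        area_mm2 = self.field_um[0] * self.field_um[1] / 1e6
        return int(round(self.density_kcells_per_mm2 * 1000.0 * area_mm2))


@dataclass
class MovieScenario:
    """Ground truth for a synthetic decorrelating movie."""

    m_pixels: int = 64
    n_frames: int = 100
    frame_interval_min: float = 10.0
    decorrelation_rate_per_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decorrelation_rate_per_min < 0:
            raise ValueError("decorrelation rate must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


#: reference parameters per class: one canonical point in the density /
#: height ranges observed for each architecture (Immature layers are
#: sparse and short, Mature layers dense and tall).
PRESETS: dict[str, LayerScenario] = {
    "immature": LayerScenario(
        class_label="Immature", density_kcells_per_mm2=2.0, layer_height_um=4.5
    ),
    "intermediate": LayerScenario(
        class_label="Intermediate", density_kcells_per_mm2=5.0, layer_height_um=6.5
    ),
    "mature": LayerScenario(
        class_label="Mature", density_kcells_per_mm2=8.0, layer_height_um=7.0
    ),
    "disorganized": LayerScenario(
        class_label="Disorganized",
        density_kcells_per_mm2=8.0,
        layer_height_um=14.0,
        nuclear_sigma_um=5.0,
    ),
    "extreme_double": LayerScenario(
        class_label="extreme_double",
        density_kcells_per_mm2=8.0,
        layer_height_um=4.0,
        nuclear_sigma_um=0.8,
    ),
    "extreme_clump": LayerScenario(
        class_label="extreme_clump",
        density_kcells_per_mm2=8.0,
        layer_height_um=4.0,
        nuclear_sigma_um=0.7,
    ),
    "extreme_pyramid": LayerScenario(
        class_label="extreme_pyramid",
        density_kcells_per_mm2=8.0,
        layer_height_um=4.0,
        nuclear_sigma_um=0.7,
    ),
}


def make_scenario(name: str, seed: int = 0, **overrides) -> LayerScenario:
    """A preset scenario with a seed and optional field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed, **overrides)


def _jittered_grid(rng: np.random.Generator, n: int, w: float, h: float, margin: float) -> np.ndarray:
    """n lateral positions on a jittered grid covering the field."""
    gx = max(1, int(math.ceil(math.sqrt(n * w / h))))
    gy = max(1, int(math.ceil(n / gx)))
    pitch_x, pitch_y = w / gx, h / gy
    xs, ys = np.meshgrid(
        (np.arange(gx) + 0.5) * pitch_x, (np.arange(gy) + 0.5) * pitch_y
    )
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    keep = rng.choice(len(pts), size=n, replace=False)
    pts = pts[np.sort(keep)]
    pts += rng.uniform(-0.35, 0.35, size=pts.shape) * np.array([pitch_x, pitch_y])
    pts[:, 0] = np.clip(pts[:, 0], margin, w - margin)
    pts[:, 1] = np.clip(pts[:, 1], margin, h - margin)
    return pts


#: lowest physically plausible centroid z (µm): half a nuclear height
#: above the substrate.
_MIN_CENTROID_Z_UM = 1.0


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, n: int, lo: float
) -> np.ndarray:
    """Normal samples truncated below at *lo* by rejection (no pile-up
    artifact at the boundary, unlike clipping)."""
    out = rng.normal(mu, sigma, n)
    for _ in range(200):
        bad = out < lo
        if not bad.any():
            break
        out[bad] = rng.normal(mu, sigma, int(bad.sum()))
    return np.maximum(out, lo)


def _sample_z(rng: np.random.Generator, scenario: LayerScenario, n: int) -> np.ndarray:
    s = scenario
    mid = s.bottom_um + 0.5 * s.layer_height_um
    label = s.class_label
    lo = _MIN_CENTROID_Z_UM
    if label in ORGANIZED_CLASSES:
        n_apical = int(round(s.apical_fraction * n))
        z_layer = _truncated_normal(rng, mid, s.nuclear_sigma_um, n - n_apical, lo)
        z_apical = _truncated_normal(rng, s.top_um + 5.0, 1.0, n_apical, lo)
        z = np.concatenate([z_layer, z_apical])
    elif label == "Disorganized":
        # a single wide spread of nuclei across many z positions
        z = _truncated_normal(rng, mid, s.nuclear_sigma_um, n, lo)
    elif label == "extreme_double":
        # an ordered double layer: two distinct narrow Gaussians
        n1 = n // 2
        z = np.concatenate(
            [
                _truncated_normal(rng, s.bottom_um + 2.0, s.nuclear_sigma_um, n1, lo),
                _truncated_normal(rng, s.bottom_um + 9.0, s.nuclear_sigma_um, n - n1, lo),
            ]
        )
    elif label == "extreme_clump":
        # sharp basal peak + tall broad Gaussian peaking above it
        n1 = int(round(0.4 * n))
        z = np.concatenate(
            [
                _truncated_normal(rng, s.bottom_um + 2.0, s.nuclear_sigma_um, n1, lo),
                _truncated_normal(rng, s.bottom_um + 10.0, 4.0, n - n1, lo),
            ]
        )
    elif label == "extreme_pyramid":
        # sharp basal peak + decaying exponential tail above it
        n1 = int(round(0.4 * n))
        z = np.concatenate(
            [
                _truncated_normal(rng, s.bottom_um + 2.0, s.nuclear_sigma_um, n1, lo),
                s.bottom_um + 3.5 + rng.exponential(4.0, n - n1),
            ]
        )
    else:  # pragma: no cover
        raise ValueError(label)
    return z


def generate_nuclei(scenario: LayerScenario) -> NucleiTable:
    """Nuclear centroids + volumes for a scenario, deterministic per seed."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_nuclei()
    w, h = scenario.field_um
    margin = min(3.0, 0.1 * min(w, h))
    xy = _jittered_grid(rng, n, w, h, margin)
    z = _sample_z(rng, scenario, n)
    volumes = rng.normal(scenario.mean_volume_um3, scenario.volume_sd_um3, n)
    volumes = np.clip(volumes, 50.0, None)
    n_debris = int(round(scenario.debris_fraction * n))
    if n_debris:
        idx = rng.choice(n, size=n_debris, replace=False)
        volumes[idx] = np.clip(
            rng.normal(scenario.debris_volume_um3, 10.0, n_debris), 20.0, None
        )
    records = [
        NucleusRecord(
            id=f"n{i:05d}",
            x_um=float(xy[i, 0]),
            y_um=float(xy[i, 1]),
            z_um=float(z[i]),
            volume_um3=float(volumes[i]),
        )
        for i in range(n)
    ]
    return NucleiTable(records=records, field_width_um=w, field_height_um=h)


def _rise(z: np.ndarray, z0: float, w: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(z - z0) / w))


def _gauss(z: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-((z - mu) ** 2) / (2 * sigma**2))


def _z_templates(scenario: LayerScenario, z: np.ndarray) -> dict[str, np.ndarray]:
    """Per-class z intensity templates: {"junction": ..., "uniform": ...}.

    The plane-sum profile of the generated stack equals (up to a constant)
    the sum of the two templates, because lateral fields are normalized to
    unit mean.
    """
    s = scenario
    b, t, h = s.bottom_um, s.top_um, s.layer_height_um
    label = s.class_label
    if label == "Immature":
        # basally weighted: flat spread cells, actin peak low in the layer
        basal = _gauss(z, b + 0.2 * h, 0.35 * h) * _rise(z, b - 0.5, 0.3)
        lateral = 0.15 * _rise(z, b, 0.3) * (1 - _rise(z, b + 0.6 * h, 0.5))
        return {"junction": lateral, "uniform": basal}
    if label == "Intermediate":
        # domed apices: one smooth peak in the apical half, no shoulder
        lateral = 0.5 * _gauss(z, b + 0.6 * h, 0.28 * h) * _rise(z, b - 0.2, 0.3)
        dome = 0.9 * _gauss(z, b + 0.75 * h, 0.20 * h) * _rise(z, b - 0.2, 0.3)
        return {"junction": lateral, "uniform": dome}
    if label == "Mature":
        # lateral plateau (the shoulder) + bright flat apical band; the
        # apical band dominates (strong apical enrichment in Mature layers)
        plateau = 0.6 * _rise(z, b + 0.5, 0.45) * (1 - _rise(z, t + 0.8, 0.3))
        apical = 0.6 * _gauss(z, t, 0.5)
        return {"junction": plateau, "uniform": apical}
    if label == "Disorganized":
        broad = _gauss(z, b + 0.5 * h, 0.35 * h)
        return {"junction": 0.2 * broad, "uniform": broad}
    # extreme configurations: the underlying organized basal sheet carries
    # an Intermediate-like actin signature
    lateral = 0.5 * _gauss(z, b + 0.6 * h, 0.28 * h) * _rise(z, b - 0.2, 0.3)
    dome = 0.9 * _gauss(z, b + 0.75 * h, 0.20 * h) * _rise(z, b - 0.2, 0.3)
    return {"junction": lateral, "uniform": dome}


def _voronoi_boundary_field(
    table: NucleiTable,
    shape: tuple[int, int],
    voxel_xy_um: float,
    ridge_sigma_um: float = 0.6,
) -> np.ndarray:
    """Lateral actin on cell-cell borders: bright ridges along the Voronoi
    boundaries of the in-layer centroids, Gaussian-profiled in distance."""
    ny, nx = shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    xs_um = (xs + 0.5) * voxel_xy_um
    ys_um = (ys + 0.5) * voxel_xy_um
    d1 = np.full(shape, np.inf)
    d2 = np.full(shape, np.inf)
    for rec in table:
        d = np.hypot(xs_um - rec.x_um, ys_um - rec.y_um)
        closer = d < d1
        d2 = np.where(closer, d1, np.minimum(d2, d))
        d1 = np.where(closer, d, d1)
    if not np.isfinite(d2).any():
        return np.ones(shape)
    gap = np.where(np.isfinite(d2), d2 - d1, np.inf)
    ridge = np.exp(-(gap**2) / (2 * ridge_sigma_um**2))
    return ridge


def generate_actin_stack(scenario: LayerScenario, table: NucleiTable) -> ImageStack:
    """Render the actin stack for a scenario + its nuclei table.

    The stack is separable per component: a z template (class-specific)
    times a lateral field — Voronoi-boundary ridges for junctional actin,
    uniform for basal/apical sheets — plus optional additive Gaussian
    noise (``noise_sd``, relative to the noiseless maximum).
    """
    s = scenario
    w, h = s.field_um
    nx = max(4, int(round(w / s.voxel_xy_um)))
    ny = max(4, int(round(h / s.voxel_xy_um)))
    if s.class_label == "Disorganized":
        z_extent = s.bottom_um + s.layer_height_um + 4.0
    else:
        z_extent = s.top_um + 6.0
    nz = int(math.ceil(z_extent / s.voxel_z_um)) + 1
    z = np.arange(nz) * s.voxel_z_um

    in_layer = [r for r in table if r.z_um <= s.top_um + 1.0]
    seeds = table.with_records(in_layer) if in_layer else table
    junction = _voronoi_boundary_field(seeds, (ny, nx), s.voxel_xy_um)
    junction = junction / max(junction.mean(), 1e-12)
    uniform = np.ones((ny, nx))

    templates = _z_templates(s, z)
    stack = (
        templates["junction"][:, None, None] * junction[None, :, :]
        + templates["uniform"][:, None, None] * uniform[None, :, :]
    )
    if s.noise_sd > 0:
        rng = np.random.default_rng(s.seed + 1009)
        stack = stack + rng.normal(0.0, s.noise_sd * stack.max(), stack.shape)
        stack = np.clip(stack, 0.0, None)
    return ImageStack(
        intensities=stack.astype(np.float32),
        voxel_xy_um=s.voxel_xy_um,
        voxel_z_um=s.voxel_z_um,
    )


def generate_field(scenario: LayerScenario) -> tuple[NucleiTable, ImageStack]:
    """Convenience: nuclei + matching actin stack for one scenario."""
    table = generate_nuclei(scenario)
    return table, generate_actin_stack(scenario, table)


def generate_movie(scenario: MovieScenario) -> Movie:
    """A movie whose expected frame-pair correlation at lag t is exp(-λt).

    Frames evolve by an AR(1) mixing rule: with ρ = exp(-λ Δt),
    F_{t+1} = ρ F_t + sqrt(1 - ρ²) ε_t, ε white noise, so the expected
    correlation between frames k steps apart is ρ^k.  λ = 0 gives a
    static movie.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    rho = math.exp(-s.decorrelation_rate_per_min * s.frame_interval_min)
    frames = np.empty((s.n_frames, s.m_pixels, s.m_pixels))
    frames[0] = rng.standard_normal((s.m_pixels, s.m_pixels))
    mix = math.sqrt(max(0.0, 1.0 - rho * rho))
    for i in range(1, s.n_frames):
        frames[i] = rho * frames[i - 1] + mix * rng.standard_normal(
            (s.m_pixels, s.m_pixels)
        )
    return Movie(frames=frames, frame_interval_min=s.frame_interval_min)


def polarization_column_stack(
    apical_to_basal: float = 1.0,
    field_um: float = 12.0,
    height_um: float = 7.0,
    bottom_um: float = 1.0,
    voxel_xy_um: float = 0.3,
    voxel_z_um: float = 0.23,
    band_sigma_um: float = 0.4,
) -> ImageStack:
    """A single-cell column with basal and apical actin bands.

    The apical band is ``apical_to_basal`` times brighter than the basal
    band — ground truth for the per-cell polarization ratio.
    """
    n = max(4, int(round(field_um / voxel_xy_um)))
    nz = int(math.ceil((bottom_um + height_um + 3.0) / voxel_z_um)) + 1
    z = np.arange(nz) * voxel_z_um
    profile = _gauss(z, bottom_um, band_sigma_um) + apical_to_basal * _gauss(
        z, bottom_um + height_um, band_sigma_um
    )
    stack = profile[:, None, None] * np.ones((n, n))[None, :, :]
    return ImageStack(
        intensities=stack.astype(np.float32),
        voxel_xy_um=voxel_xy_um,
        voxel_z_um=voxel_z_um,
    )
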