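"""Apical-basal (z) profile operations.

Reduces the 3D inputs to 1D functions of z: a nuclear-count histogram and a
summed actin intensity curve, then derives the physical layer bounds and
per-cell apical/basal polarization from them.  The layer bottom is the
first z where the actin profile rises above a density-dependent fraction
(20-50%) of its peak; the top is the last z above a second fraction
(60-80%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import (
    AnalysisConfig,
    ImageStack,
    NucleusRecord,
    NucleiTable,
    ZProfile,
    smoothing_window_samples,
)

logger = logging.getLogger("epilayer")


class LayerBoundsError(ValueError):
    """Raised when no layer bounds can be located in an actin profile."""


@dataclass
class LayerBounds:
    """Physical z of the layer bottom and top, with the fractions used."""

    bottom_um: float
    top_um: float
    bottom_fraction: float
    top_fraction: float

    def __post_init__(self) -> None:
        if not (self.bottom_um < self.top_um):
            raise ValueError(
                f"layer bottom ({self.bottom_um}) must lie below top ({self.top_um})"
            )

    @property
    def height_um(self) -> float:
        return self.top_um - self.bottom_um

    @property
    def mid_um(self) -> float:
        return 0.5 * (self.bottom_um + self.top_um)


@dataclass
class PolarizationProfile:
    """Per-cell cylindrical-core actin profile and its apical/basal peaks.

    The core profile of a single cell has two peaks, one at the basal and
    one at the apical surface; ``ratio`` is apical peak value / basal peak
    value (undefined, and flagged, when fewer than two peaks are found).
    """

    profile: ZProfile
    basal_peak_um: float | None
    apical_peak_um: float | None
    ratio: float | None

    @property
    def is_valid(self) -> bool:
        return self.ratio is not None


def filter_nuclei(
    table: NucleiTable, sd_multiplier: float = 1.5
) -> tuple[NucleiTable, list[str]]:
    """Remove debris: objects too small to be nuclei.

    The cutoff is set per table: ``mean(volume) - sd_multiplier * SD(volume)``
    (sample SD); records with volume at or below the cutoff are excluded.
    There is no upper cutoff, because genuinely large nuclei occur in
    culture.  A stricter multiplier of 1.0 also removes pyknotic nuclei.

    Returns the filtered table and the list of excluded record ids.
    """
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")
    if len(table) == 0:
        raise ValueError("cannot filter an empty nuclei table")
    if len(table) == 1:
        logger.info("single-record table: volume SD undefined, no filtering applied")
        return table, []
    volumes = table.volumes()
    sd = float(np.std(volumes, ddof=1))
    if sd == 0.0:
        # Without variance there can be no outlying debris; the <= rule
        # would otherwise delete every nucleus.
        logger.info("zero volume variance: no filtering applied")
        return table, []
    cutoff = float(np.mean(volumes)) - sd_multiplier * sd
    kept = [r for r in table if r.volume_um3 > cutoff]
    excluded = [r.id for r in table if r.volume_um3 <= cutoff]
    if excluded:
        logger.info(
            "volume filter (cutoff %.1f um^3, multiplier %.2g) excluded %d of %d nuclei",
            cutoff,
            sd_multiplier,
            len(excluded),
            len(table),
        )
    return table.with_records(kept), excluded


def nuclear_z_histogram(table: NucleiTable, bin_um: float = 1.0) -> ZProfile:
    """Histogram nuclear centroid z positions in half-open bins from z = 0.

    Bins are ``[k*bin_um, (k+1)*bin_um)``; the returned profile carries bin
    centers and integer counts summing to the record count.
    """
    if bin_um <= 0:
        raise ValueError("bin width must be positive")
    zs = table.zs()
    if zs.size == 0:
        edges = np.array([0.0, bin_um])
        counts = np.zeros(1)
    else:
        n_bins = max(1, int(np.floor(zs.max() / bin_um)) + 1)
        edges = np.arange(n_bins + 1) * bin_um
        # np.histogram's last bin is closed; add a guard bin so every bin
        # used is half-open, then verify nothing landed in the guard.
        counts, _ = np.histogram(zs, bins=np.append(edges, edges[-1] + bin_um))
        counts = counts[:-1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ZProfile(z_um=centers, values=counts, kind="nuclear_histogram", bin_um=bin_um)


def actin_z_profile(stack: ImageStack) -> ZProfile:
    """Project the actin signal onto z by summing each plane, peak = 1."""
    sums = (
        stack.intensities.reshape(stack.n_planes, -1).astype(np.float64).sum(axis=1)
    )
    peak = sums.max()
    if peak <= 0:
        raise ValueError("no actin signal: stack sums to zero")
    return ZProfile(z_um=stack.z_um(), values=sums / peak, kind="actin_intensity")


def bound_fractions(
    density_kcells_per_mm2: float, config: AnalysisConfig
) -> tuple[float, float]:
    """Map nuclear density to the bottom/top peak fractions.

    Denser fields have more lateral actin relative to the basal signal, so
    both thresholds scale up linearly between the density anchors and are
    clamped to their admissible ranges.
    """
    d_lo, d_hi = config.density_anchor_lo, config.density_anchor_hi
    t = (density_kcells_per_mm2 - d_lo) / (d_hi - d_lo)
    b_lo, b_hi = config.bottom_fraction_range
    t_lo, t_hi = config.top_fraction_range
    bottom = min(max(b_lo + (b_hi - b_lo) * t, b_lo), b_hi)
    top = min(max(t_lo + (t_hi - t_lo) * t, t_lo), t_hi)
    return bottom, top


def _first_upward_crossing(z: np.ndarray, v: np.ndarray, level: float) -> float | None:
    """z of the first upward crossing of *level*, linearly interpolated."""
    for i in range(len(v) - 1):
        if v[i] <= level < v[i + 1]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            return float(z[i] + frac * (z[i + 1] - z[i]))
    return None


def _last_downward_crossing(z: np.ndarray, v: np.ndarray, level: float) -> float | None:
    """z of the last downward crossing of *level*, linearly interpolated."""
    for i in range(len(v) - 2, -1, -1):
        if v[i] > level >= v[i + 1]:
            frac = (v[i] - level) / (v[i] - v[i + 1])
            return float(z[i] + frac * (z[i + 1] - z[i]))
    if v[-1] > level:
        # profile still above the level at the stack top
        return float(z[-1])
    return None


def find_layer_bounds(
    actin: ZProfile,
    density_kcells_per_mm2: float,
    config: AnalysisConfig | None = None,
) -> LayerBounds:
    """Locate the physical bottom and top of the cell layer.

    Bottom: first z where the normalized actin profile rises above the
    bottom fraction of the peak.  Top: last z above the top fraction.
    Crossings are linearly interpolated between z samples.
    """
    config = config or AnalysisConfig()
    if density_kcells_per_mm2 < 0:
        raise ValueError("density must be non-negative")
    if actin.kind != "actin_intensity":
        raise ValueError("layer bounds require an actin intensity profile")
    bottom_fraction, top_fraction = bound_fractions(density_kcells_per_mm2, config)
    z, v = actin.z_um, actin.values / actin.values.max()
    bottom = _first_upward_crossing(z, v, bottom_fraction)
    top = _last_downward_crossing(z, v, top_fraction)
    spacing = float(np.median(np.diff(z))) if len(z) > 1 else 0.0
    if (
        bottom is None
        or top is None
        or not (bottom < top)
        or (top - bottom) < spacing  # thinner than the z-sampling: a spike
    ):
        raise LayerBoundsError(
            "layer bounds undetectable: no suitable threshold crossings "
            f"(fractions {bottom_fraction:.2f}/{top_fraction:.2f})"
        )
    return LayerBounds(
        bottom_um=bottom,
        top_um=top,
        bottom_fraction=bottom_fraction,
        top_fraction=top_fraction,
    )


def smooth_profile(values: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing with edge-shrinking window (length preserved)."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(window) / window
    padded = np.pad(values, (window // 2, window - 1 - window // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def profile_peaks(
    values: np.ndarray,
    prominence_fraction: float = 0.05,
    smoothing_window: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima of a (smoothed) profile above a relative prominence.

    Returns (indices, peak values on the smoothed profile), ordered by
    position.
    """
    smoothed = smooth_profile(np.asarray(values, dtype=float), smoothing_window)
    if smoothed.max() <= 0:
        return np.array([], dtype=int), np.array([])
    idx, _props = find_peaks(smoothed, prominence=prominence_fraction * smoothed.max())
    return idx, smoothed[idx]


def polarization_ratio(
    stack: ImageStack,
    nucleus: NucleusRecord,
    radius_um: float = 2.0,
    config: AnalysisConfig | None = None,
) -> PolarizationProfile:
    """Per-cell apical/basal actin polarization from a cylindrical core.

    A disk of ``radius_um`` around the nuclear centroid (chosen small
    enough to avoid cell-cell borders) is summed plane by plane and
    normalized to peak 1.  The two most prominent local maxima are the
    basal (lower z) and apical (higher z) surface signals; the ratio is
    apical / basal peak value.
    """
    config = config or AnalysisConfig()
    if radius_um <= 0:
        raise ValueError("cylinder radius must be positive")
    nz, ny, nx = stack.shape
    cx = nucleus.x_um / stack.voxel_xy_um
    cy = nucleus.y_um / stack.voxel_xy_um
    r_px = radius_um / stack.voxel_xy_um
    if not (r_px <= cx <= nx - 1 - r_px and r_px <= cy <= ny - 1 - r_px):
        raise ValueError(
            f"cylinder around nucleus {nucleus.id!r} extends outside the field"
        )
    yy, xx = np.ogrid[:ny, :nx]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    sums = stack.intensities[:, disk].sum(axis=1).astype(float)
    if sums.max() <= 0:
        raise ValueError("no actin signal inside the cylindrical core")
    values = sums / sums.max()
    profile = ZProfile(z_um=stack.z_um(), values=values, kind="actin_intensity")
    window = smoothing_window_samples(config, stack.voxel_z_um)
    idx, heights = profile_peaks(
        values, config.peak_prominence_fraction, smoothing_window=window
    )
    if len(idx) < 2:
        logger.warning(
            "polarization ratio undefined for nucleus %r: %d peak(s) found",
            nucleus.id,
            len(idx),
        )
        return PolarizationProfile(profile, None, None, None)
    # two most prominent = two tallest after the prominence cut, by z order
    top2 = idx[np.argsort(heights)[-2:]]
    basal_i, apical_i = int(top2.min()), int(top2.max())
    basal_z, apical_z = profile.z_um[basal_i], profile.z_um[apical_i]
    smoothed = smooth_profile(values, window)
    ratio = float(smoothed[apical_i] / smoothed[basal_i])
    return PolarizationProfile(profile, float(basal_z), float(apical_z), ratio)
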