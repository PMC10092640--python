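"""Core data containers shared across the analysis pipeline.

The pipeline consumes two experimental inputs: a table of segmented nuclear
centroids (x, y, z in µm plus nuclear volume in µm³) exported by a
segmentation tool, and a single-channel 3D F-actin intensity stack with
known voxel dimensions.  Everything downstream is expressed in physical
units (µm, µm³, 10³ cells/mm²); plane index 0 of a stack is the basal-most
(substrate-facing) plane and z increases apically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("epilayer")

#: z-spacing above which axial sampling is considered too coarse for
#: reliable layer-bound detection (µm).
MAX_RECOMMENDED_VOXEL_Z_UM = 0.5


@dataclass(frozen=True)
class NucleusRecord:
    """A single segmented nucleus: centroid position and volume."""

    id: str
    x_um: float
    y_um: float
    z_um: float
    volume_um3: float

    def __post_init__(self) -> None:
        for name in ("x_um", "y_um", "z_um"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite coordinate {name} for nucleus {self.id!r}")
        if not (self.volume_um3 > 0):
            raise ValueError(
                f"nuclear volume must be positive, got {self.volume_um3} for {self.id!r}"
            )


@dataclass
class NucleiTable:
    """Ordered collection of nuclei from one imaged field.

    ``field_width_um`` / ``field_height_um`` give the lateral extent of the
    imaged field; they are needed to convert counts to densities.
    """

    records: list[NucleusRecord]
    field_width_um: float
    field_height_um: float

    def __post_init__(self) -> None:
        if not (self.field_width_um > 0 and self.field_height_um > 0):
            raise ValueError("field dimensions must be positive")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("nucleus record ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def area_um2(self) -> float:
        return self.field_width_um * self.field_height_um

    def zs(self) -> np.ndarray:
        return np.array([r.z_um for r in self.records], dtype=float)

    def volumes(self) -> np.ndarray:
        return np.array([r.volume_um3 for r in self.records], dtype=float)

    def density_kcells_per_mm2(self) -> float:
        """Nuclear density in 10³ cells/mm² (the field's standard unit)."""
        return len(self) / self.area_um2 * 1000.0

    def with_records(self, records: Iterable[NucleusRecord]) -> "NucleiTable":
        return replace(self, records=list(records))


@dataclass
class ImageStack:
    """Single-channel 3D intensity stack indexed (z, y, x).

    Plane 0 is the physically lowest (basal-most) plane; physical
    z of plane *k* is ``k * voxel_z_um``.
    """

    intensities: np.ndarray
    voxel_xy_um: float
    voxel_z_um: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"stack must be 3D (z, y, x), got shape {self.intensities.shape}"
            )
        if self.intensities.shape[0] == 0:
            raise ValueError("stack has zero planes")
        if not (self.voxel_xy_um > 0 and self.voxel_z_um > 0):
            raise ValueError("voxel dimensions must be positive")
        if self.voxel_z_um > MAX_RECOMMENDED_VOXEL_Z_UM:
            logger.warning(
                "z-spacing %.3g um exceeds the recommended maximum of %.2g um; "
                "layer bounds may be unreliable",
                self.voxel_z_um,
                MAX_RECOMMENDED_VOXEL_Z_UM,
            )

    @property
    def n_planes(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def z_um(self) -> np.ndarray:
        """Physical z position of each plane (µm)."""
        return np.arange(self.n_planes) * self.voxel_z_um

    @property
    def depth_um(self) -> float:
        return (self.n_planes - 1) * self.voxel_z_um


@dataclass
class ZProfile:
    """A 1D function of apical-basal position.

    Either a nuclear-count histogram (``kind="nuclear_histogram"``, values
    are integer counts per bin, ``z_um`` holds bin centers) or a summed
    actin intensity curve (``kind="actin_intensity"``, values normalized so
    the peak is 1, ``z_um`` holds plane positions).
    """

    z_um: np.ndarray
    values: np.ndarray
    kind: str
    bin_um: float | None = None

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.z_um.shape != self.values.shape:
            raise ValueError("z_um and values must have the same shape")
        if self.z_um.size > 1 and not np.all(np.diff(self.z_um) > 0):
            raise ValueError("z_um must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")
        if self.kind not in ("nuclear_histogram", "actin_intensity"):
            raise ValueError(f"unknown profile kind {self.kind!r}")

    @property
    def peak_z_um(self) -> float:
        """z position of the profile maximum."""
        return float(self.z_um[int(np.argmax(self.values))])

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class AnalysisConfig:
    """Tunable cutoffs of the layer-architecture analysis.

    Defaults are calibrated for MDCK-like cultures; other epithelial lines
    may need minor adjustments (all cutoffs are exposed here for that
    reason).
    """

    #: nuclei with volume <= mean - multiplier*SD are excluded as debris;
    #: use 1.0 for a stricter cutoff that also removes pyknotic nuclei.
    volume_sd_multiplier: float = 1.5
    #: bin width of the nuclear z histogram (µm).
    histogram_bin_um: float = 1.0
    #: admissible range of the peak fraction defining the layer bottom.
    bottom_fraction_range: tuple[float, float] = (0.20, 0.50)
    #: admissible range of the peak fraction defining the layer top.
    top_fraction_range: tuple[float, float] = (0.60, 0.80)
    #: densities (10³ cells/mm²) at which the bound fractions hit the low /
    #: high ends of their ranges.
    density_anchor_lo: float = 2.0
    density_anchor_hi: float = 8.0
    #: significance level of the 1-vs-2 Gaussian extra-sum-of-squares F-test.
    gaussian_alpha: float = 0.05
    #: a single nuclear Gaussian wider than this (µm) means Disorganized.
    wide_sigma_um: float = 3.0
    #: maximum SD (µm) of the basal component for it to count as a
    #: monolayer-sharp nuclear peak in the two-component organized call;
    #: half of wide_sigma_um (a basal layer must be sharper than the
    #: widest acceptable single-layer distribution).
    monolayer_sigma_um: float = 1.5
    #: two components are "separate" iff mu2 - mu1 >= factor*(sigma1+sigma2).
    separation_factor: float = 1.0
    #: moving-average window for profile smoothing, in samples; None means
    #: the number of samples spanning 1 µm.
    derivative_smoothing_window: int | None = None
    #: how far below the detected layer bottom the maturity derivative
    #: window extends (µm), so the basal actin rise is retained.
    derivative_basal_pad_um: float = 2.0
    #: minimum filtered nucleus count for a classification attempt.
    min_nuclei: int = 10
    #: edge length of subregion tiles (µm).
    subregion_um: float = 100.0
    #: cylinder radius for per-cell polarization profiles (µm).
    cylinder_radius_um: float = 2.0
    #: minimum relative contrast of the junctional actin plane for
    #: watershed segmentation; below it a centroid-Voronoi fallback is used.
    junction_contrast_threshold: float = 0.05
    #: peak prominence, as a fraction of the profile maximum.
    peak_prominence_fraction: float = 0.05
    #: seed recorded with runs for reproducibility (generators take their
    #: own seeds).
    seed: int | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.bottom_fraction_range, self.top_fraction_range):
            if not (0 < lo <= hi < 1):
                raise ValueError("bound fraction ranges must lie in (0, 1)")
        if not (self.histogram_bin_um > 0):
            raise ValueError("histogram bin width must be positive")
        if self.min_nuclei < 3:
            raise ValueError("min_nuclei must be at least 3")
        if not (self.density_anchor_hi > self.density_anchor_lo):
            raise ValueError("density anchors must satisfy hi > lo")


def smoothing_window_samples(
    config: AnalysisConfig, sample_spacing_um: float
) -> int:
    """Resolve the moving-average window (in samples) for a given spacing."""
    if config.derivative_smoothing_window is not None:
        return max(1, int(config.derivative_smoothing_window))
    return max(1, int(round(1.0 / sample_spacing_um)))
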