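"""Layer-architecture classification.

Implements the decision flowchart: a 1-vs-2 Gaussian model selection on the
nuclear z histogram decides Organized vs Disorganized; Organized layers are
subclassified Immature / Intermediate / Mature from the relationship
between the actin intensity profile and the nuclear distribution; nuclei
are partitioned into in-layer and apical counts; the same machinery runs on
square subregions to map architectural heterogeneity across a field.

Classes, in order of maturity:

* Immature — flat, spread cells; the actin peak sits at/below the nuclear
  peak or in the basal half of the layer.
* Intermediate — cobblestone cells with domed apices; a monopeaked actin
  profile above the nuclear peak.
* Mature — columnar cells with flat apices; the actin profile shows a
  lateral "shoulder" before an apical band, detected as a two-peaked first
  derivative with right/left peak ratio > 1.
* Disorganized — no discernible single layer: a wide single nuclear
  Gaussian or two overlapping ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import optimize, stats

from .core import (
    AnalysisConfig,
    ImageStack,
    NucleiTable,
    ZProfile,
    smoothing_window_samples,
)
from .zprofiles import (
    LayerBounds,
    actin_z_profile,
    filter_nuclei,
    find_layer_bounds,
    nuclear_z_histogram,
    smooth_profile,
)

logger = logging.getLogger("epilayer")

#: label ordering used for deterministic tie-breaking (least to most mature)
MATURITY_ORDER = ["Disorganized", "Immature", "Intermediate", "Mature"]


class InsufficientSignalError(RuntimeError):
    """Raised when neither Gaussian model can be fitted to the histogram."""


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian component of the nuclear z distribution."""

    mu_um: float
    sigma_um: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.sigma_um > 0):
            raise ValueError("sigma must be positive")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((z - self.mu_um) ** 2) / (2 * self.sigma_um**2))


@dataclass
class GaussianFitResult:
    """1- and 2-component least-squares fits to the nuclear histogram.

    ``selected`` is "two" iff the extra-sum-of-squares F-test rejects the
    single-Gaussian model at the configured alpha.
    """

    one: GaussianComponent
    one_rss: float
    two: tuple[GaussianComponent, GaussianComponent]  # ordered by mu
    two_rss: float
    selected: str  # "one" | "two"
    f_statistic: float
    p_value: float

    @property
    def components(self) -> tuple[GaussianComponent, ...]:
        return self.two if self.selected == "two" else (self.one,)


@dataclass
class PlanarSummary:
    """Field-level summary of in-plane cell shape (see :mod:`epilayer.planar`)."""

    n_cells: int
    mean_area_um2: float
    mean_circularity: float


@dataclass
class LayerReport:
    """Full classification output for one field or subregion."""

    label: str  # Immature | Intermediate | Mature | Disorganized | Insufficient
    n_total: int
    n_filtered: int
    excluded_ids: list[str] = field(default_factory=list)
    bounds: LayerBounds | None = None
    height_um: float | None = None
    density_kcells_per_mm2: float | None = None
    n_in_layer: int | None = None
    n_apical: int | None = None
    fit: GaussianFitResult | None = None
    organized_mode: str | None = None  # single | with_apical
    actin_peak_um: float | None = None
    nuclear_peak_um: float | None = None
    derivative_peak_ratio: float | None = None
    planar: PlanarSummary | None = None

    @property
    def is_organized(self) -> bool:
        return self.label in ("Immature", "Intermediate", "Mature")


@dataclass
class SubregionReport:
    """Per-tile classifications of a field plus the modal label."""

    tile_um: float
    n_tiles_x: int
    n_tiles_y: int
    reports: list[list[LayerReport]]  # [iy][ix]
    mode_label: str

    def labels(self) -> list[str]:
        return [r.label for row in self.reports for r in row]


def _gauss1(z, a, mu, sigma):
    return a * np.exp(-((z - mu) ** 2) / (2 * sigma**2))


def _gauss1_jac(z, a, mu, sigma):
    e = np.exp(-((z - mu) ** 2) / (2 * sigma**2))
    return np.stack(
        [e, a * e * (z - mu) / sigma**2, a * e * (z - mu) ** 2 / sigma**3], axis=1
    )


def _gauss2(z, a1, mu1, s1, a2, mu2, s2):
    return _gauss1(z, a1, mu1, s1) + _gauss1(z, a2, mu2, s2)


def _gauss2_jac(z, a1, mu1, s1, a2, mu2, s2):
    return np.concatenate(
        [_gauss1_jac(z, a1, mu1, s1), _gauss1_jac(z, a2, mu2, s2)], axis=1
    )


_JAC = {_gauss1: _gauss1_jac, _gauss2: _gauss2_jac}


def _fit(model, z, counts, p0, bounds, sigma):
    popt, _ = optimize.curve_fit(
        model,
        z,
        counts,
        p0=p0,
        bounds=bounds,
        sigma=sigma,
        absolute_sigma=True,
        jac=_JAC[model],
        maxfev=5000,
    )
    rss = float(np.sum(((counts - model(z, *popt)) / sigma) ** 2))
    return popt, rss


def fit_nuclear_gaussians(hist: ZProfile, alpha: float = 0.05) -> GaussianFitResult:
    """Fit 1- and 2-Gaussian curves to the binned nuclear counts and compare.

    Both models are least-squares curve fits to (bin center, count) pairs,
    weighted by the counting noise of each bin (sigma_i = sqrt(max(c_i, 1)),
    without which the comparison grossly over-selects the two-component
    model on peaked histograms).  The two-component fit uses a fixed
    multi-start initialization (second mean at the histogram mode + 3, 6,
    9 µm, plus a degenerate start at the one-component solution), keeping
    the lowest-RSS result — deterministic given the input.  Models are
    compared with the extra-sum-of-squares F-test on the weighted RSS;
    "two" is selected iff p < alpha.
    """
    if hist.kind != "nuclear_histogram":
        raise ValueError("gaussian fits require a nuclear histogram profile")
    z = hist.z_um
    counts = hist.values.astype(float)
    total = counts.sum()
    if total <= 0:
        raise InsufficientSignalError("empty nuclear histogram")

    zmin, zmax = float(z.min()), float(z.max())
    span = max(zmax - zmin, 1.0)
    amax = float(counts.max())
    lower1 = [0.0, zmin - 2.0, 0.1]
    upper1 = [5 * amax + 1, zmax + 2.0, 2 * span]

    sigma = np.sqrt(np.maximum(counts, 1.0))

    mean0 = float(np.sum(z * counts) / total)
    sd0 = float(np.sqrt(np.sum(counts * (z - mean0) ** 2) / total)) or 0.5
    sd0 = max(sd0, 0.3)
    one_popt = one_rss = None
    try:
        one_popt, one_rss = _fit(
            _gauss1, z, counts, [amax, mean0, sd0], (lower1, upper1), sigma
        )
    except RuntimeError:
        logger.warning("single-Gaussian fit did not converge")

    mode_z = float(z[int(np.argmax(counts))])
    starts = [
        [amax, mode_z, 1.0, 0.5 * amax, mode_z + off, 1.0]
        for off in (3.0, 6.0, 9.0, -3.0, -6.0, -9.0)
    ]
    # start at the two tallest distinct local maxima, when they exist
    from scipy.signal import find_peaks

    pk, _ = find_peaks(np.concatenate([[0.0], counts, [0.0]]))
    pk = pk - 1
    if len(pk) >= 2:
        top2 = pk[np.argsort(counts[pk])[-2:]]
        za, zb = sorted(float(z[i]) for i in top2)
        starts.append([counts[top2].max(), za, 1.0, counts[top2].min(), zb, 1.0])
    if one_popt is not None:
        a, mu, s = one_popt
        # degenerate start: nested model, guarantees two_rss <= one_rss
        starts.append([a, mu, s, 1e-3 * max(amax, 1.0), mu + s, max(s, 0.5)])
    lower2, upper2 = lower1 * 2, upper1 * 2
    best = None
    for p0 in starts:
        p0 = [min(max(v, lo), hi) for v, lo, hi in zip(p0, lower2, upper2)]
        try:
            popt, rss = _fit(_gauss2, z, counts, p0, (lower2, upper2), sigma)
        except RuntimeError:
            continue
        if best is None or rss < best[1]:
            best = (popt, rss)
    if one_popt is None and best is None:
        raise InsufficientSignalError(
            "neither Gaussian model converged on the nuclear histogram"
        )
    if one_popt is None:
        # fall back: treat the better 2-fit's dominant component as the 1-fit
        popt, rss = best
        dom = popt[:3] if popt[0] >= popt[3] else popt[3:]
        one_popt, one_rss = dom, float(np.sum(((counts - _gauss1(z, *dom)) / sigma) ** 2))
    if best is None:
        a, mu, s = one_popt
        best = ([a, mu, s, 0.0, mu + s, s], one_rss)
    two_popt, two_rss = best
    two_rss = min(two_rss, one_rss)  # nested models: numerical guard

    n = len(z)
    df1, df2 = n - 3, n - 6
    if df2 <= 0:
        f_stat, p_value = 0.0, 1.0
    elif two_rss <= 0:
        f_stat, p_value = np.inf, 0.0
    else:
        f_stat = ((one_rss - two_rss) / (df1 - df2)) / (two_rss / df2)
        p_value = float(stats.f.sf(f_stat, df1 - df2, df2))

    one_comp = GaussianComponent(float(one_popt[1]), float(one_popt[2]), float(one_popt[0]))
    c_a = GaussianComponent(float(two_popt[1]), float(two_popt[2]), float(two_popt[0]))
    c_b = GaussianComponent(float(two_popt[4]), float(two_popt[5]), float(two_popt[3]))
    two_comp = tuple(sorted((c_a, c_b), key=lambda c: c.mu_um))
    selected = "two" if p_value < alpha else "one"
    return GaussianFitResult(
        one=one_comp,
        one_rss=float(one_rss),
        two=two_comp,
        two_rss=float(two_rss),
        selected=selected,
        f_statistic=float(f_stat),
        p_value=float(p_value),
    )


def _mixture_sd_um(components: tuple[GaussianComponent, GaussianComponent]) -> float:
    """Overall SD of the two-component mixture (mass-weighted)."""
    masses = np.array([c.amplitude * c.sigma_um for c in components])
    if masses.sum() <= 0:
        return float(max(c.sigma_um for c in components))
    w = masses / masses.sum()
    mus = np.array([c.mu_um for c in components])
    sigmas = np.array([c.sigma_um for c in components])
    mean = float(np.sum(w * mus))
    var = float(np.sum(w * (sigmas**2 + mus**2)) - mean**2)
    return float(np.sqrt(max(var, 0.0)))


def classify_organization(
    fit: GaussianFitResult, config: AnalysisConfig | None = None
) -> tuple[str, str | None]:
    """Organized vs Disorganized from the nuclear Gaussian fit.

    A single sharp peak is an organized layer; a single wide peak is
    Disorganized.  When the two-component model is selected, Organized
    means a monolayer is discernible at the bottom: either the two peaks
    are clearly separate with a monolayer-sharp basal component (a layer
    with cells on top — no matter the shape of the extralayer mass), or
    the two components jointly still form one sharp peak (a least-squares
    split of a single layer).  Broad, overlapping components — nuclei
    spanning many z positions — are Disorganized.

    Returns (label, organized_mode) where organized_mode is "single" or
    "with_apical" (None when Disorganized).
    """
    config = config or AnalysisConfig()
    if fit.selected == "one":
        if fit.one.sigma_um <= config.wide_sigma_um:
            return "Organized", "single"
        return "Disorganized", None
    lo, hi = fit.two
    separated = (hi.mu_um - lo.mu_um) >= config.separation_factor * (
        lo.sigma_um + hi.sigma_um
    )
    basal_sharp = lo.sigma_um <= config.monolayer_sigma_um
    if separated and basal_sharp:
        return "Organized", "with_apical"
    if _mixture_sd_um(fit.two) <= config.wide_sigma_um:
        return "Organized", "single"
    if basal_sharp:
        return "Organized", "with_apical"
    return "Disorganized", None


def classify_maturity(
    actin: ZProfile,
    bounds: LayerBounds,
    nuclear_peak_um: float,
    config: AnalysisConfig | None = None,
) -> tuple[str, float | None]:
    """Immature / Intermediate / Mature for an Organized layer.

    Immature: the actin peak is at/below the nuclear peak, or closer to the
    layer bottom than the top.  Otherwise the smoothed first derivative of
    the actin profile (from just below the layer bottom to the top, so the
    basal rise is retained) is examined: two peaks with right/left value
    ratio > 1 indicate the lateral shoulder + apical band of a Mature
    layer; a single peak or ratio <= 1 means Intermediate.

    Returns (label, derivative_peak_ratio) — the ratio is None when the
    derivative is not two-peaked.
    """
    config = config or AnalysisConfig()
    actin_peak = actin.peak_z_um
    basal_half = (actin_peak - bounds.bottom_um) < (bounds.top_um - actin_peak)
    if nuclear_peak_um >= actin_peak or basal_half:
        return "Immature", None

    spacing = float(np.median(np.diff(actin.z_um)))
    window = smoothing_window_samples(config, spacing)
    smoothed = smooth_profile(actin.values, window)
    deriv = np.gradient(smoothed, actin.z_um)
    lo = bounds.bottom_um - config.derivative_basal_pad_um
    mask = (actin.z_um >= lo) & (actin.z_um <= bounds.top_um)
    if mask.sum() < 3:
        return "Intermediate", None
    d = deriv[mask]
    if d.max() <= 0:
        return "Intermediate", None
    from scipy.signal import find_peaks

    idx, props = find_peaks(d, prominence=config.peak_prominence_fraction * d.max())
    if len(idx) < 2:
        return "Intermediate", None
    if len(idx) > 2:
        keep = np.sort(idx[np.argsort(props["prominences"])[-2:]])
    else:
        keep = idx
    left, right = d[keep[0]], d[keep[1]]
    ratio = float(right / left) if left > 0 else np.inf
    return ("Mature" if ratio > 1 else "Intermediate"), ratio


def count_layer_membership(
    table: NucleiTable,
    fit: GaussianFitResult,
    bounds: LayerBounds,
    mode: str | None = None,
) -> tuple[int, int]:
    """Partition nuclei of an Organized field into in-layer and apical.

    Two-component fit: each nucleus goes to the component whose fitted
    curve is higher at its z; the basal (lower-mean) component is the
    layer.  Single component: nuclei more than 3 sigma above the mean are
    apical.  ``mode`` ("single" | "with_apical") overrides which rule is
    used — a two-component fit that the organization call merged back into
    one sharp peak is counted with the single-component rule.  The counts
    always partition the table.
    """
    zs = table.zs()
    if len(zs) == 0:
        return 0, 0
    use_two = fit.selected == "two" if mode is None else mode == "with_apical"
    if use_two:
        basal, upper = fit.two
        in_layer = int(np.sum(basal(zs) >= upper(zs)))
        return in_layer, len(zs) - in_layer
    mu, sigma = fit.one.mu_um, fit.one.sigma_um
    apical = int(np.sum(zs > mu + 3 * sigma))
    return len(zs) - apical, apical


def _stage(name: str):
    """Context manager adding the pipeline stage name to raised errors."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        try:
            yield
        except (ValueError, RuntimeError) as exc:
            exc.args = (f"[{name}] {exc}",) + exc.args[1:]
            raise

    return cm()


def classify_layer(
    table: NucleiTable,
    stack: ImageStack,
    config: AnalysisConfig | None = None,
    include_planar: bool = False,
) -> LayerReport:
    """Run the full classification pipeline on one field.

    filter → nuclear histogram → actin profile → layer bounds → Gaussian
    model selection → organization → (if Organized) maturity → in-layer /
    apical membership → metrics.  Fields with fewer than ``min_nuclei``
    filtered nuclei are labeled Insufficient.
    """
    config = config or AnalysisConfig()
    n_total = len(table)
    with _stage("filter_nuclei"):
        filtered, excluded = filter_nuclei(table, config.volume_sd_multiplier)
    if len(filtered) < config.min_nuclei:
        return LayerReport(
            label="Insufficient",
            n_total=n_total,
            n_filtered=len(filtered),
            excluded_ids=excluded,
            density_kcells_per_mm2=len(filtered) / table.area_um2 * 1000.0,
        )
    with _stage("nuclear_z_histogram"):
        hist = nuclear_z_histogram(filtered, config.histogram_bin_um)
    with _stage("actin_z_profile"):
        actin = actin_z_profile(stack)
    density_filtered = len(filtered) / table.area_um2 * 1000.0
    with _stage("find_layer_bounds"):
        bounds = find_layer_bounds(actin, density_filtered, config)
    with _stage("fit_nuclear_gaussians"):
        fit = fit_nuclear_gaussians(hist, config.gaussian_alpha)
    org, mode = classify_organization(fit, config)

    # nuclear peak: mean of the basal fitted component (the layer itself)
    if mode == "with_apical":
        nuclear_peak = fit.two[0].mu_um
    else:
        nuclear_peak = fit.one.mu_um
    actin_peak = actin.peak_z_um

    report = LayerReport(
        label="Disorganized",
        n_total=n_total,
        n_filtered=len(filtered),
        excluded_ids=excluded,
        bounds=bounds,
        height_um=bounds.height_um,
        density_kcells_per_mm2=density_filtered,
        fit=fit,
        organized_mode=mode,
        actin_peak_um=actin_peak,
        nuclear_peak_um=nuclear_peak,
    )
    if org == "Disorganized":
        return report

    with _stage("classify_maturity"):
        label, ratio = classify_maturity(actin, bounds, nuclear_peak, config)
    n_in, n_apical = count_layer_membership(filtered, fit, bounds, mode=mode)
    report.label = label
    report.derivative_peak_ratio = ratio
    report.n_in_layer = n_in
    report.n_apical = n_apical
    # density of the layer proper: in-layer nuclei over the field area
    report.density_kcells_per_mm2 = n_in / table.area_um2 * 1000.0

    if include_planar:
        from . import planar

        with _stage("planar"):
            seg = planar.segment_plane(stack, filtered, bounds, config)
            metrics = planar.shape_metrics(seg, stack.voxel_xy_um)
        if metrics.n_cells:
            report.planar = PlanarSummary(
                n_cells=metrics.n_cells,
                mean_area_um2=metrics.mean_area_um2,
                mean_circularity=metrics.mean_circularity,
            )
    return report


def _mode_label(labels: list[str]) -> str:
    """Most frequent non-Insufficient label; ties break toward maturity."""
    counted = [l for l in labels if l != "Insufficient"]
    if not counted:
        return "Insufficient"
    best = None
    for label in MATURITY_ORDER:  # later entries win ties
        c = counted.count(label)
        if c and (best is None or c >= best[1]):
            best = (label, c)
    return best[0]


def classify_subregions(
    table: NucleiTable,
    stack: ImageStack,
    tile_um: float | None = None,
    config: AnalysisConfig | None = None,
) -> SubregionReport:
    """Tile the field into squares and classify each independently.

    Tiles are laid out from the field origin with half-open boundaries;
    nuclei are assigned by centroid, the stack is cropped laterally per
    tile.  The modal tile label (Insufficient tiles excluded, ties broken
    toward the more mature label) summarizes the field.
    """
    config = config or AnalysisConfig()
    tile_um = tile_um if tile_um is not None else config.subregion_um
    if table.field_width_um < tile_um or table.field_height_um < tile_um:
        raise ValueError(
            f"field ({table.field_width_um} x {table.field_height_um} um) is "
            f"smaller than one {tile_um} um tile"
        )
    ntx = int(table.field_width_um // tile_um)
    nty = int(table.field_height_um // tile_um)
    reports: list[list[LayerReport]] = []
    for iy in range(nty):
        row = []
        y0, y1 = iy * tile_um, (iy + 1) * tile_um
        for ix in range(ntx):
            x0, x1 = ix * tile_um, (ix + 1) * tile_um
            recs = [r for r in table if x0 <= r.x_um < x1 and y0 <= r.y_um < y1]
            shifted = [
                dc_replace(r, x_um=r.x_um - x0, y_um=r.y_um - y0) for r in recs
            ]
            sub_table = NucleiTable(
                records=shifted, field_width_um=tile_um, field_height_um=tile_um
            )
            px0 = int(round(x0 / stack.voxel_xy_um))
            px1 = int(round(x1 / stack.voxel_xy_um))
            py0 = int(round(y0 / stack.voxel_xy_um))
            py1 = int(round(y1 / stack.voxel_xy_um))
            sub_stack = ImageStack(
                intensities=stack.intensities[:, py0:py1, px0:px1],
                voxel_xy_um=stack.voxel_xy_um,
                voxel_z_um=stack.voxel_z_um,
            )
            try:
                row.append(classify_layer(sub_table, sub_stack, config))
            except (ValueError, RuntimeError) as exc:
                logger.warning("tile (%d, %d) failed: %s", ix, iy, exc)
                row.append(
                    LayerReport(
                        label="Insufficient",
                        n_total=len(sub_table),
                        n_filtered=len(sub_table),
                    )
                )
        reports.append(row)
    mode = _mode_label([r.label for row in reports for r in row])
    return SubregionReport(
        tile_um=tile_um,
        n_tiles_x=ntx,
        n_tiles_y=nty,
        reports=reports,
        mode_label=mode,
    )
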