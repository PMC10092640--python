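"""Gaussian model selection, organization/maturity rules, membership, tiling."""

import numpy as np
import pytest

from epilayer import classifier, synthgen, zprofiles
from epilayer.classifier import (
    GaussianComponent,
    GaussianFitResult,
    classify_maturity,
    classify_organization,
    count_layer_membership,
    fit_nuclear_gaussians,
)
from epilayer.core import AnalysisConfig, ImageStack, ZProfile
from epilayer.zprofiles import LayerBounds

from tests.conftest import TEST_SCALE, table_from_z


def _hist(zs):
    return zprofiles.nuclear_z_histogram(table_from_z(zs))


def _fake_fit(selected, components, one=None):
    comps = tuple(sorted(components, key=lambda c: c.mu_um))
    one = one or comps[0]
    return GaussianFitResult(
        one=one,
        one_rss=1.0,
        two=comps if len(comps) == 2 else (comps[0], comps[0]),
        two_rss=0.5,
        selected=selected,
        f_statistic=1.0,
        p_value=0.01 if selected == "two" else 0.5,
    )


# --- Gaussian fitting -------------------------------------------------------


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_unimodal_histogram_selects_one_and_recovers_mean(seed):
    rng = np.random.default_rng(seed)
    zs = rng.normal(4, 1, 200).clip(0.1)
    fit = fit_nuclear_gaussians(_hist(zs))
    assert fit.selected == "one"
    assert abs(fit.one.mu_um - 4.0) < 0.3


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_bimodal_histogram_selects_two_and_recovers_means(seed):
    rng = np.random.default_rng(seed)
    zs = np.concatenate(
        [rng.normal(3, 1, 140).clip(0.1), rng.normal(12, 1, 60)]
    )
    fit = fit_nuclear_gaussians(_hist(zs))
    assert fit.selected == "two"
    lo, hi = fit.two
    assert abs(lo.mu_um - 3.0) < 0.5
    assert abs(hi.mu_um - 12.0) < 0.5


@pytest.mark.parametrize("seed", range(8))
def test_two_fit_never_worse_than_one_fit(seed):
    """Nested models: the 2-component weighted RSS never exceeds the 1-component."""
    rng = np.random.default_rng(seed)
    zs = rng.uniform(0, 15, int(rng.integers(20, 300)))
    fit = fit_nuclear_gaussians(_hist(zs))
    assert fit.two_rss <= fit.one_rss + 1e-9


def test_empty_histogram_is_insufficient_signal():
    from epilayer.classifier import InsufficientSignalError
    from epilayer.core import NucleiTable

    hist = zprofiles.nuclear_z_histogram(NucleiTable([], 10, 10))
    with pytest.raises(InsufficientSignalError):
        fit_nuclear_gaussians(hist)


# --- organization rules -----------------------------------------------------


def test_two_distinct_narrow_peaks_organized():
    """A double layer: two sharp, well-separated nuclear peaks."""
    fit = _fake_fit(
        "two",
        [GaussianComponent(3.0, 0.8, 10.0), GaussianComponent(10.0, 0.8, 10.0)],
    )
    label, mode = classify_organization(fit)
    assert label == "Organized" and mode == "with_apical"


def test_sharp_basal_peak_with_broad_mass_above_organized():
    """A clump of cells above a monolayer: sharp basal + tall broad upper."""
    fit = _fake_fit(
        "two",
        [GaussianComponent(3.0, 0.7, 12.0), GaussianComponent(11.0, 4.0, 5.0)],
    )
    label, mode = classify_organization(fit)
    assert label == "Organized" and mode == "with_apical"


def test_wide_single_gaussian_disorganized():
    fit = _fake_fit("one", [GaussianComponent(6.0, 4.0, 10.0)])
    label, mode = classify_organization(fit, AnalysisConfig(wide_sigma_um=3.0))
    assert label == "Disorganized" and mode is None


def test_narrow_single_gaussian_organized():
    fit = _fake_fit("one", [GaussianComponent(4.0, 1.0, 10.0)])
    label, mode = classify_organization(fit)
    assert label == "Organized" and mode == "single"


def test_two_broad_overlapping_components_disorganized():
    """Nuclei spanning many z positions split into two broad humps."""
    fit = _fake_fit(
        "two",
        [GaussianComponent(5.0, 2.5, 8.0), GaussianComponent(10.0, 3.0, 8.0)],
    )
    label, mode = classify_organization(fit)
    assert label == "Disorganized"


def test_falsely_split_sharp_peak_still_organized():
    """Two nearly coincident narrow components merge back to one sharp peak."""
    fit = _fake_fit(
        "two",
        [GaussianComponent(4.3, 1.1, 40.0), GaussianComponent(4.8, 0.5, 30.0)],
    )
    label, mode = classify_organization(fit)
    assert label == "Organized" and mode == "single"


# --- maturity rules ---------------------------------------------------------


def _actin_profile(z, values):
    values = np.asarray(values, float)
    return ZProfile(z, values / values.max(), "actin_intensity")


def test_actin_peak_below_nuclear_peak_is_immature():
    z = np.arange(0, 10, 0.25)
    prof = _actin_profile(z, np.exp(-((z - 4.5) ** 2) / 2.0))
    bounds = LayerBounds(1.0, 8.0, 0.3, 0.7)
    label, ratio = classify_maturity(prof, bounds, nuclear_peak_um=5.5)
    assert label == "Immature" and ratio is None


def test_basal_half_actin_peak_is_immature_even_below_nuclei():
    z = np.arange(0, 10, 0.25)
    prof = _actin_profile(z, np.exp(-((z - 2.0) ** 2) / 1.0))
    bounds = LayerBounds(1.0, 8.0, 0.3, 0.7)
    label, _ = classify_maturity(prof, bounds, nuclear_peak_um=1.0)
    assert label == "Immature"


def test_monopeaked_profile_above_nuclei_is_intermediate():
    z = np.arange(0, 10, 0.25)
    prof = _actin_profile(z, np.exp(-((z - 5.5) ** 2) / 3.0))
    bounds = LayerBounds(1.0, 7.5, 0.3, 0.7)
    label, ratio = classify_maturity(prof, bounds, nuclear_peak_um=3.5)
    assert label == "Intermediate"


def test_shouldered_profile_is_mature_with_ratio_above_one():
    """Lateral plateau then a brighter apical rise: two-peaked derivative."""
    z = np.arange(0, 11, 0.25)
    plateau = 0.55 / (1 + np.exp(-(z - 1.5) / 0.4))
    apical = 0.9 * np.exp(-((z - 8.0) ** 2) / (2 * 0.5**2))
    prof = _actin_profile(z, plateau + apical)
    bounds = LayerBounds(1.5, 8.4, 0.4, 0.7)
    label, ratio = classify_maturity(prof, bounds, nuclear_peak_um=4.0)
    assert label == "Mature"
    assert ratio is not None and ratio > 1


def test_shoulder_ratio_matches_brute_force_derivative_scan():
    """The reported ratio equals a direct difference-quotient peak scan."""
    config = AnalysisConfig()
    z = np.arange(0, 11, 0.25)
    plateau = 0.55 / (1 + np.exp(-(z - 1.5) / 0.4))
    apical = 0.9 * np.exp(-((z - 8.0) ** 2) / (2 * 0.5**2))
    prof = _actin_profile(z, plateau + apical)
    bounds = LayerBounds(1.5, 8.4, 0.4, 0.7)
    _, ratio = classify_maturity(prof, bounds, nuclear_peak_um=4.0, config=config)

    # oracle: same smoothing, independent derivative + local-max scan
    window = 4  # samples spanning 1 um at dz = 0.25
    kernel = np.ones(window) / window
    padded = np.pad(prof.values, (window // 2, window - 1 - window // 2), mode="edge")
    sm = np.convolve(padded, kernel, mode="valid")
    d = np.gradient(sm, z)
    lo = bounds.bottom_um - config.derivative_basal_pad_um
    sel = (z >= lo) & (z <= bounds.top_um)
    dz, dsel = z[sel], d[sel]
    peaks = [
        i
        for i in range(1, len(dsel) - 1)
        if dsel[i] > dsel[i - 1] and dsel[i] >= dsel[i + 1]
    ]
    heights = sorted(((dsel[i], dz[i]) for i in peaks), reverse=True)[:2]
    (h_a, z_a), (h_b, z_b) = heights
    left, right = ((h_a, h_b) if z_a < z_b else (h_b, h_a))
    assert ratio == pytest.approx(right / left, rel=1e-6)


# --- membership counting ----------------------------------------------------


def test_single_component_within_two_sigma_no_apical(rng):
    zs = np.clip(rng.normal(4, 1, 100), 2.0, 6.0)
    fit = _fake_fit("one", [GaussianComponent(4.0, 1.0, 20.0)])
    n_in, n_ap = count_layer_membership(
        table_from_z(zs), fit, LayerBounds(1, 8, 0.3, 0.7)
    )
    assert (n_in, n_ap) == (100, 0)


def test_planted_two_component_counts_match_brute_force(rng):
    zs = np.concatenate([rng.normal(3, 1, 100).clip(0.1), rng.normal(12, 1, 10)])
    basal = GaussianComponent(3.0, 1.0, 20.0)
    upper = GaussianComponent(12.0, 1.0, 2.0)
    fit = _fake_fit("two", [basal, upper])
    n_in, n_ap = count_layer_membership(
        table_from_z(zs), fit, LayerBounds(1, 6, 0.3, 0.7)
    )
    # brute-force likelihood comparison per nucleus
    expected_in = sum(1 for z in zs if basal(np.array(z)) >= upper(np.array(z)))
    assert n_in == expected_in == 100
    assert n_ap == 10


@pytest.mark.parametrize("seed", range(5))
def test_membership_partitions_table(seed):
    rng = np.random.default_rng(seed)
    zs = rng.uniform(0, 15, 80)
    fit = _fake_fit(
        "two", [GaussianComponent(3, 1, 10.0), GaussianComponent(11, 2, 5.0)]
    )
    n_in, n_ap = count_layer_membership(
        table_from_z(zs), fit, LayerBounds(1, 8, 0.3, 0.7)
    )
    assert n_in + n_ap == 80


def test_adding_apical_nuclei_never_decreases_apical_count(rng):
    base = list(rng.normal(3, 1, 60).clip(0.1))
    fit = _fake_fit(
        "two", [GaussianComponent(3, 1, 10.0), GaussianComponent(12, 1, 2.0)]
    )
    bounds = LayerBounds(1, 6, 0.3, 0.7)
    prev = 0
    for extra in range(0, 12, 3):
        zs = base + [12.0 + 0.1 * k for k in range(extra)]
        _, n_ap = count_layer_membership(table_from_z(zs), fit, bounds)
        assert n_ap >= prev
        prev = n_ap


# --- end-to-end pipeline ----------------------------------------------------


@pytest.mark.parametrize(
    "preset,expected",
    [
        ("immature", "Immature"),
        ("intermediate", "Intermediate"),
        ("mature", "Mature"),
        ("disorganized", "Disorganized"),
    ],
)
def test_classify_layer_recovers_generating_class(preset, expected):
    scen = synthgen.make_scenario(preset, seed=11, **TEST_SCALE)
    table, stack = synthgen.generate_field(scen)
    report = classifier.classify_layer(table, stack)
    assert report.label == expected
    if report.is_organized:
        assert report.n_in_layer + report.n_apical == report.n_filtered
        assert report.height_um == pytest.approx(
            report.bounds.top_um - report.bounds.bottom_um
        )


def test_small_field_is_insufficient():
    scen = synthgen.make_scenario(
        "mature", seed=0, field_um=(25.0, 25.0), voxel_xy_um=1.0, voxel_z_um=0.25
    )
    table, stack = synthgen.generate_field(scen)
    table = table.with_records(table.records[:5])
    report = classifier.classify_layer(table, stack)
    assert report.label == "Insufficient"


def test_apical_fraction_counted(rng):
    """Planted apical nuclei are recovered by the membership partition."""
    scen = synthgen.make_scenario(
        "intermediate", seed=4, apical_fraction=0.1, noise_sd=0.0, **{
            k: v for k, v in TEST_SCALE.items() if k != "noise_sd"
        }
    )
    table, stack = synthgen.generate_field(scen)
    report = classifier.classify_layer(table, stack)
    assert int(round(0.1 * scen.n_nuclei())) > 0
    # the volume filter may drop a nucleus at random; compare against the
    # planted apical nuclei that survive it
    filtered, _ = zprofiles.filter_nuclei(table, 1.5)
    planted_surviving = sum(1 for r in filtered if r.z_um > scen.top_um + 2.0)
    assert report.organized_mode == "with_apical"
    assert report.n_apical == planted_surviving


# --- subregions -------------------------------------------------------------


def test_subregion_tiling_arithmetic():
    """A 300x300 um field with 100 um tiles gives a 3x3 grid of 9 tiles."""
    scen = synthgen.make_scenario(
        "mature", seed=2, field_um=(300.0, 300.0), voxel_xy_um=1.0,
        voxel_z_um=0.25, noise_sd=0.05,
    )
    table, stack = synthgen.generate_field(scen)
    rep = classifier.classify_subregions(table, stack, tile_um=100.0)
    assert rep.n_tiles_x == rep.n_tiles_y == 3
    assert len(rep.labels()) == 9
    n_assigned = sum(r.n_total for row in rep.reports for r in row)
    assert n_assigned == len(table)  # half-open tiles partition the nuclei


def test_homogeneous_field_mode_matches_full_field_label():
    scen = synthgen.make_scenario(
        "mature", seed=2, field_um=(300.0, 300.0), voxel_xy_um=1.0,
        voxel_z_um=0.25, noise_sd=0.05,
    )
    table, stack = synthgen.generate_field(scen)
    rep = classifier.classify_subregions(table, stack, tile_um=100.0)
    full = classifier.classify_layer(table, stack)
    assert rep.mode_label == full.label == "Mature"
    assert all(l == "Mature" for l in rep.labels())


def test_mosaic_mode_is_majority_label(rng):
    """5 organized-template tiles + 4 wide-nuclei tiles: the mode is the
    organized label."""
    from epilayer.core import NucleusRecord, NucleiTable

    tile, field = 100.0, 300.0
    records = []
    k = 0
    for iy in range(3):
        for ix in range(3):
            wide = (3 * iy + ix) % 2 == 1  # 4 disorganized tiles
            for _ in range(80):
                x = ix * tile + rng.uniform(2, tile - 2)
                y = iy * tile + rng.uniform(2, tile - 2)
                if wide:  # overlapping-bimodal spread of nuclei
                    z = rng.normal(5.0, 2.5) if rng.random() < 0.5 else rng.normal(10.0, 2.5)
                else:
                    z = rng.normal(4.5, 1.0)
                records.append(
                    NucleusRecord(f"n{k}", x, y, max(z, 1.0), float(rng.normal(500, 50)))
                )
                k += 1
    table = NucleiTable(records, field, field)
    scen = synthgen.make_scenario(
        "mature", seed=0, field_um=(field, field), voxel_xy_um=1.0,
        voxel_z_um=0.25, noise_sd=0.0,
    )
    stack = synthgen.generate_actin_stack(scen, table)
    rep = classifier.classify_subregions(table, stack, tile_um=tile)
    labels = rep.labels()
    assert labels.count("Disorganized") == 4
    assert rep.mode_label == "Mature"


def test_field_smaller_than_tile_rejected():
    scen = synthgen.make_scenario(
        "mature", seed=0, field_um=(50.0, 50.0), voxel_xy_um=1.0, voxel_z_um=0.25
    )
    table, stack = synthgen.generate_field(scen)
    with pytest.raises(ValueError, match="smaller"):
        classifier.classify_subregions(table, stack, tile_um=100.0)


def test_mode_tie_breaks_toward_more_mature():
    assert classifier._mode_label(["Mature", "Disorganized"]) == "Mature"
    assert classifier._mode_label(["Immature", "Intermediate"]) == "Intermediate"
    assert classifier._mode_label(["Insufficient"]) == "Insufficient"
    assert (
        classifier._mode_label(["Disorganized", "Disorganized", "Mature"])
        == "Disorganized"
    )
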