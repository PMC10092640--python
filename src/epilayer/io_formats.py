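"""File I/O for the formats the pipeline touches.

Nuclei tables are CSV (the default column dialect follows the common
commercial segmentation export: "Position X/Y/Z" and "Volume", already in
µm/µm³); stacks and movies are multi-page single-channel TIFF; reports are
JSON (structured) or CSV (one row per field/subregion); configuration is
YAML.  Ingestion never reorders, filters, or rescales data beyond the
declared unit conversion — filtering is a separate, logged pipeline stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .classifier import (
    GaussianComponent,
    GaussianFitResult,
    LayerReport,
    PlanarSummary,
    SubregionReport,
)
from .core import AnalysisConfig, ImageStack, NucleusRecord, NucleiTable, ZProfile
from .dynamics import Movie
from .zprofiles import LayerBounds

logger = logging.getLogger("epilayer")

_FIELD_RE = re.compile(
    r"#\s*field_width_um\s*=\s*([0-9.eE+-]+)\s*,\s*field_height_um\s*=\s*([0-9.eE+-]+)"
)


class TableFormatError(ValueError):
    """A nuclei CSV is missing a required column or has malformed cells."""


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping (and declared units) of a nuclei CSV export."""

    x: str = "Position X"
    y: str = "Position Y"
    z: str = "Position Z"
    volume: str = "Volume"
    id: str | None = "ID"
    #: multiply positions / volumes by these to obtain µm / µm³
    position_scale: float = 1.0
    volume_scale: float = 1.0


DEFAULT_DIALECT = TableDialect()


def _resolve_column(columns: list[str], wanted: str) -> str | None:
    """Exact match first, then prefix match (handles unit suffixes like
    'Position X [µm]')."""
    if wanted in columns:
        return wanted
    matches = [c for c in columns if c.startswith(wanted)]
    return matches[0] if len(matches) == 1 else None


def read_nuclei_table(
    path: str | Path,
    dialect: TableDialect | None = None,
    field_width_um: float | None = None,
    field_height_um: float | None = None,
) -> NucleiTable:
    """Read a nuclei centroid CSV into a :class:`NucleiTable`.

    Row order is preserved and values are converted to µm/µm³ per the
    dialect's declared units; nothing is filtered.  Field dimensions come
    from the arguments, from a ``# field_width_um=...,field_height_um=...``
    comment line written by :func:`write_nuclei_table`, or — as a last
    resort, with a warning — from the maximal coordinates in the table.
    """
    dialect = dialect or DEFAULT_DIALECT
    path = Path(path)
    header_w = header_h = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _FIELD_RE.match(line)
            if m:
                header_w, header_h = float(m.group(1)), float(m.group(2))
    df = pd.read_csv(path, comment="#")
    columns = list(df.columns)
    resolved = {}
    for logical in ("x", "y", "z", "volume"):
        wanted = getattr(dialect, logical)
        col = _resolve_column(columns, wanted)
        if col is None:
            raise TableFormatError(
                f"cannot resolve required column {logical!r} "
                f"(looked for {wanted!r}) in {path.name}: columns are {columns}"
            )
        resolved[logical] = col
    id_col = _resolve_column(columns, dialect.id) if dialect.id else None

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(columns, row))
        try:
            vals = {k: float(rowd[c]) for k, c in resolved.items()}
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"non-numeric cell in row {i} of {path.name}: {exc}"
            ) from exc
        rid = str(rowd[id_col]) if id_col else str(i)
        records.append(
            NucleusRecord(
                id=rid,
                x_um=vals["x"] * dialect.position_scale,
                y_um=vals["y"] * dialect.position_scale,
                z_um=vals["z"] * dialect.position_scale,
                volume_um3=vals["volume"] * dialect.volume_scale,
            )
        )
    w = field_width_um if field_width_um is not None else header_w
    h = field_height_um if field_height_um is not None else header_h
    if w is None or h is None:
        xs = [r.x_um for r in records] or [1.0]
        ys = [r.y_um for r in records] or [1.0]
        w = w if w is not None else float(np.ceil(max(xs)))
        h = h if h is not None else float(np.ceil(max(ys)))
        logger.warning(
            "field dimensions not provided; inferred %.0f x %.0f um from centroids",
            w,
            h,
        )
    return NucleiTable(records=records, field_width_um=w, field_height_um=h)


def write_nuclei_table(
    table: NucleiTable, path: str | Path, dialect: TableDialect | None = None
) -> None:
    """Write a nuclei table as CSV (field dimensions in a comment line)."""
    dialect = dialect or DEFAULT_DIALECT
    path = Path(path)
    df = pd.DataFrame(
        {
            (dialect.id or "ID"): [r.id for r in table],
            dialect.x: [r.x_um / dialect.position_scale for r in table],
            dialect.y: [r.y_um / dialect.position_scale for r in table],
            dialect.z: [r.z_um / dialect.position_scale for r in table],
            dialect.volume: [r.volume_um3 / dialect.volume_scale for r in table],
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# field_width_um={table.field_width_um},"
            f"field_height_um={table.field_height_um}\n"
        )
        df.to_csv(fh, index=False)


def read_stack(
    path: str | Path, voxel_xy_um: float, voxel_z_um: float, channel: int | None = None
) -> ImageStack:
    """Read a multi-page single-channel TIFF as an :class:`ImageStack`.

    Plane 0 is taken to be the physically lowest (basal-most) plane.
    Multi-channel files require an explicit ``channel``.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim == 4:
        if channel is None:
            raise ValueError(
                f"{Path(path).name} has {data.shape[1]} channels; pass channel="
            )
        data = data[:, channel]
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError(f"{Path(path).name}: expected a non-empty z-stack")
    return ImageStack(intensities=data, voxel_xy_um=voxel_xy_um, voxel_z_um=voxel_z_um)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(str(path), stack.intensities)


def read_movie(path: str | Path, frame_interval_min: float) -> Movie:
    """Read a multi-frame TIFF time-lapse."""
    data = tifffile.imread(str(path))
    if data.ndim != 3:
        raise ValueError(f"{Path(path).name}: expected a 2D time series")
    return Movie(frames=data, frame_interval_min=frame_interval_min)


def write_movie(movie: Movie, path: str | Path) -> None:
    tifffile.imwrite(str(path), movie.frames.astype(np.float32))


def write_profile_csv(profile: ZProfile, path: str | Path) -> None:
    """Two-column (z_um, value) CSV of a z profile, for plotting."""
    pd.DataFrame({"z_um": profile.z_um, "value": profile.values}).to_csv(
        path, index=False
    )


# --- report serialization ---------------------------------------------------


def _bounds_to_dict(b: LayerBounds | None):
    return None if b is None else dataclasses.asdict(b)


def _fit_to_dict(f: GaussianFitResult | None):
    if f is None:
        return None
    return {
        "one": dataclasses.asdict(f.one),
        "one_rss": f.one_rss,
        "two": [dataclasses.asdict(c) for c in f.two],
        "two_rss": f.two_rss,
        "selected": f.selected,
        "f_statistic": f.f_statistic,
        "p_value": f.p_value,
    }


def report_to_dict(report: LayerReport) -> dict:
    return {
        "label": report.label,
        "n_total": report.n_total,
        "n_filtered": report.n_filtered,
        "excluded_ids": list(report.excluded_ids),
        "bounds": _bounds_to_dict(report.bounds),
        "height_um": report.height_um,
        "density_kcells_per_mm2": report.density_kcells_per_mm2,
        "n_in_layer": report.n_in_layer,
        "n_apical": report.n_apical,
        "fit": _fit_to_dict(report.fit),
        "organized_mode": report.organized_mode,
        "actin_peak_um": report.actin_peak_um,
        "nuclear_peak_um": report.nuclear_peak_um,
        "derivative_peak_ratio": report.derivative_peak_ratio,
        "planar": None if report.planar is None else dataclasses.asdict(report.planar),
    }


def report_from_dict(d: dict) -> LayerReport:
    bounds = d.get("bounds")
    fit = d.get("fit")
    planar = d.get("planar")
    return LayerReport(
        label=d["label"],
        n_total=d["n_total"],
        n_filtered=d["n_filtered"],
        excluded_ids=list(d.get("excluded_ids") or []),
        bounds=None if bounds is None else LayerBounds(**bounds),
        height_um=d.get("height_um"),
        density_kcells_per_mm2=d.get("density_kcells_per_mm2"),
        n_in_layer=d.get("n_in_layer"),
        n_apical=d.get("n_apical"),
        fit=None
        if fit is None
        else GaussianFitResult(
            one=GaussianComponent(**fit["one"]),
            one_rss=fit["one_rss"],
            two=tuple(GaussianComponent(**c) for c in fit["two"]),
            two_rss=fit["two_rss"],
            selected=fit["selected"],
            f_statistic=fit["f_statistic"],
            p_value=fit["p_value"],
        ),
        organized_mode=d.get("organized_mode"),
        actin_peak_um=d.get("actin_peak_um"),
        nuclear_peak_um=d.get("nuclear_peak_um"),
        derivative_peak_ratio=d.get("derivative_peak_ratio"),
        planar=None if planar is None else PlanarSummary(**planar),
    )


_CSV_FIELDS = [
    "region",
    "label",
    "n_total",
    "n_filtered",
    "height_um",
    "density_kcells_per_mm2",
    "n_in_layer",
    "n_apical",
    "actin_peak_um",
    "nuclear_peak_um",
    "derivative_peak_ratio",
]


def _report_csv_row(region: str, r: LayerReport) -> dict:
    d = report_to_dict(r)
    row = {k: d.get(k) for k in _CSV_FIELDS if k != "region"}
    row["region"] = region
    return row


def write_report(
    report: LayerReport | SubregionReport, path: str | Path, format: str = "json"
) -> None:
    """Serialize a report (full-field or subregion grid) to JSON or CSV.

    The CSV form of a subregion report has one row per tile plus a summary
    row carrying the modal label.
    """
    path = Path(path)
    if format == "json":
        if isinstance(report, SubregionReport):
            payload = {
                "tile_um": report.tile_um,
                "n_tiles_x": report.n_tiles_x,
                "n_tiles_y": report.n_tiles_y,
                "mode_label": report.mode_label,
                "tiles": [
                    [report_to_dict(r) for r in row] for row in report.reports
                ],
            }
        else:
            payload = report_to_dict(report)
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        if isinstance(report, SubregionReport):
            rows = [
                _report_csv_row(f"tile_{ix}_{iy}", r)
                for iy, row in enumerate(report.reports)
                for ix, r in enumerate(row)
            ]
            summary = {k: None for k in _CSV_FIELDS}
            summary["region"] = "summary"
            summary["label"] = report.mode_label
            rows.append(summary)
        else:
            rows = [_report_csv_row("field", report)]
        pd.DataFrame(rows, columns=_CSV_FIELDS).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> LayerReport | SubregionReport:
    """Read back a JSON report written by :func:`write_report`."""
    payload = json.loads(Path(path).read_text())
    if "tiles" in payload:
        return SubregionReport(
            tile_um=payload["tile_um"],
            n_tiles_x=payload["n_tiles_x"],
            n_tiles_y=payload["n_tiles_y"],
            mode_label=payload["mode_label"],
            reports=[
                [report_from_dict(d) for d in row] for row in payload["tiles"]
            ],
        )
    return report_from_dict(payload)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML (None → defaults)."""
    if path is None:
        return AnalysisConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("bottom_fraction_range", "top_fraction_range"):
        if key in data:
            data[key] = tuple(data[key])
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["bottom_fraction_range"] = list(config.bottom_fraction_range)
    d["top_fraction_range"] = list(config.top_fraction_range)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
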