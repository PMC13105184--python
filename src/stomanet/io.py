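"""Readers and writers for centroid tables, metadata, and results.

Centroid files are the delimited tables an ImageJ "Measure" export with the
centroid option produces: a header row with ``X`` and ``Y`` columns (case
insensitive, extra columns ignored), one row per stoma, coordinates in
micrometres by default or in pixels via ``unit_scale`` (µm per coordinate
unit). Metadata is one CSV row per sample: sample_id, species, site,
area_mm2, diameter_um.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stomanet.patterns import (
    DuplicatePointError,
    ObservationWindow,
    PointPattern,
    StomatalSample,
)


class FormatError(ValueError):
    """Input table does not match the expected dialect."""


METADATA_COLUMNS = ("sample_id", "species", "site", "area_mm2", "diameter_um")


@dataclass(frozen=True)
class MetadataRecord:
    sample_id: str
    species: str
    site: str
    area_mm2: float
    diameter_um: float


def _sniff_sep(path: Path) -> str:
    """Comma/tab auto-detection from the header line."""
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def infer_window(
    points_mm: np.ndarray, declared_area_mm2: float | None
) -> tuple[ObservationWindow, str]:
    """Observation window for a centroid cloud, plus a policy label.

    With a declared observation area, the tight bounding box is expanded by
    an equal margin ``m`` on all four sides so that
    ``(w + 2m)(h + 2m) = area`` — the smallest symmetric window of the
    declared area containing every point. Without one, the tight bounding
    box is used (label ``"tight_bbox"``), which underestimates the true
    crop area and is therefore flagged to the manifest by callers.
    """
    if len(points_mm) == 0:
        area = declared_area_mm2 if declared_area_mm2 else 1.0
        return ObservationWindow.square(area), (
            "declared_area" if declared_area_mm2 else "default_unit"
        )
    x_min, y_min = points_mm.min(axis=0)
    x_max, y_max = points_mm.max(axis=0)
    w = x_max - x_min
    h = y_max - y_min
    if declared_area_mm2 is not None:
        bbox_area = w * h
        if bbox_area >= declared_area_mm2:
            warnings.warn(
                f"point bounding box area {bbox_area:.4g} mm^2 exceeds declared area "
                f"{declared_area_mm2:.4g} mm^2; using tight bounding box",
                stacklevel=2,
            )
        else:
            # (w+2m)(h+2m) = A  =>  4m^2 + 2(w+h)m + wh - A = 0
            m = (-(w + h) + np.sqrt((w + h) ** 2 - 4 * (w * h - declared_area_mm2))) / 4
            return (
                ObservationWindow(x_min - m, y_min - m, x_max + m, y_max + m),
                "declared_area",
            )
    if w == 0 or h == 0:
        pad = max(w, h, 1e-6) / 2  # degenerate bbox (collinear points)
        return (
            ObservationWindow(x_min - pad, y_min - pad, x_max + pad, y_max + pad),
            "tight_bbox_padded",
        )
    return ObservationWindow(x_min, y_min, x_max, y_max), "tight_bbox"


def read_centroid_table(
    path: str | Path,
    unit_scale: float = 1.0,
    window: ObservationWindow | str = "auto",
    declared_area_mm2: float | None = None,
    jitter_um: float | None = None,
    rng: np.random.Generator | None = None,
) -> PointPattern:
    """Read one sample's centroid coordinates into a point pattern (mm).

    Each coordinate is multiplied by ``unit_scale`` (µm per input unit; 1
    for calibrated µm exports, the pixel size for raw pixel exports) and
    converted to mm. ``window="auto"`` infers the window via
    :func:`infer_window`; coincident duplicate rows raise unless
    ``jitter_um`` is given, in which case each duplicated point is displaced
    by uniform noise of that amplitude (resolved with ``rng``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if unit_scale <= 0:
        raise ValueError(f"unit_scale must be positive, got {unit_scale}")
    try:
        table = pd.read_csv(path, sep=_sniff_sep(path))
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=["X", "Y"])
    cols = {c.strip().lower(): c for c in table.columns}
    for needed in ("x", "y"):
        if needed not in cols:
            raise FormatError(
                f"{path.name}: no {needed.upper()!r} column in header {list(table.columns)}"
            )
    xy = table[[cols["x"], cols["y"]]].apply(pd.to_numeric, errors="coerce")
    if xy.isna().any().any():
        bad = xy.columns[xy.isna().any()][0]
        raise FormatError(f"{path.name}: unparsable values in column {bad!r}")
    points_mm = xy.to_numpy(dtype=float) * unit_scale / 1000.0
    if len(points_mm) == 0:
        warnings.warn(f"{path.name}: empty centroid table (n=0)", stacklevel=2)
    if len(points_mm) > 1:
        uniq = np.unique(points_mm, axis=0)
        if len(uniq) < len(points_mm):
            if jitter_um is None:
                raise DuplicatePointError(
                    f"{path.name}: {len(points_mm) - len(uniq)} coincident centroid row(s); "
                    "pass jitter_um to resolve"
                )
            rng = rng if rng is not None else np.random.default_rng(0)
            amp = jitter_um / 1000.0
            _, first = np.unique(points_mm, axis=0, return_index=True)
            dup_mask = np.ones(len(points_mm), dtype=bool)
            dup_mask[first] = False
            points_mm[dup_mask] += rng.uniform(-amp, amp, size=(dup_mask.sum(), 2))
    if window == "auto":
        win, _policy = infer_window(points_mm, declared_area_mm2)
    elif isinstance(window, ObservationWindow):
        win = window
    else:
        raise ValueError(f"window must be an ObservationWindow or 'auto', got {window!r}")
    return PointPattern(points_mm, win)


def write_centroid_table(pattern: PointPattern, path: str | Path) -> None:
    """Write a pattern's coordinates back out in µm with X,Y headers."""
    pts_um = pattern.points * 1000.0
    pd.DataFrame({"X": pts_um[:, 0], "Y": pts_um[:, 1]}).to_csv(
        path, index=False, float_format="%.9f"
    )


def read_metadata_table(path: str | Path) -> list[MetadataRecord]:
    """Read the per-sample metadata CSV, validating every record."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_sep(path))
    cols = {c.strip().lower(): c for c in table.columns}
    missing = [c for c in METADATA_COLUMNS if c not in cols]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    records: list[MetadataRecord] = []
    seen: set[str] = set()
    for row in table.itertuples(index=False):
        row = dict(zip(table.columns, row))
        sid = str(row[cols["sample_id"]]).strip()
        if sid in seen:
            raise FormatError(f"{path.name}: duplicated sample_id {sid!r}")
        seen.add(sid)
        area = float(row[cols["area_mm2"]])
        diam = float(row[cols["diameter_um"]])
        if area <= 0:
            raise FormatError(f"{path.name}: sample {sid!r} has non-positive area_mm2 {area}")
        if diam <= 0:
            raise FormatError(f"{path.name}: sample {sid!r} has non-positive diameter_um {diam}")
        records.append(
            MetadataRecord(
                sample_id=sid,
                species=str(row[cols["species"]]).strip(),
                site=str(row[cols["site"]]).strip(),
                area_mm2=area,
                diameter_um=diam,
            )
        )
    return records


@dataclass(frozen=True)
class ReconciliationReport:
    """Join diagnostics: ids present on only one side of the pattern/metadata join."""

    orphan_patterns: tuple[str, ...]
    unmatched_metadata: tuple[str, ...]

    def is_clean(self) -> bool:
        return not self.orphan_patterns and not self.unmatched_metadata


def assemble_samples(
    patterns: Mapping[str, PointPattern], metadata: Sequence[MetadataRecord]
) -> tuple[list[StomatalSample], ReconciliationReport]:
    """Join centroid patterns with metadata records by sample id.

    Mismatches on either side are reported, not fatal: the returned samples
    are the clean inner join.
    """
    meta_ids = {m.sample_id for m in metadata}
    samples = [
        StomatalSample(
            sample_id=m.sample_id,
            species=m.species,
            site=m.site,
            pattern=patterns[m.sample_id],
            stomatal_diameter_um=m.diameter_um,
        )
        for m in metadata
        if m.sample_id in patterns
    ]
    report = ReconciliationReport(
        orphan_patterns=tuple(sorted(set(patterns) - meta_ids)),
        unmatched_metadata=tuple(sorted(meta_ids - set(patterns))),
    )
    return samples, report


def write_results(
    per_sample: pd.DataFrame,
    summary: Mapping,
    manifest: Mapping,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the per-sample table, study summary, and JSON run manifest.

    MST lengths appear in both µm and mm (mm = µm / 1000 exactly). An empty
    study yields header-only tables and an ``n_samples = 0`` summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_sample = per_sample.copy()
    if "mst_length_um" in per_sample.columns:
        per_sample["mst_length_mm"] = per_sample["mst_length_um"] / 1000.0
    paths = {
        "per_sample": out / "per_sample.csv",
        "summary": out / "study_summary.csv",
        "manifest": out / "run_manifest.json",
    }
    per_sample.to_csv(paths["per_sample"], index=False, float_format="%.9g")
    pd.DataFrame([dict(summary)]).to_csv(paths["summary"], index=False, float_format="%.9g")
    with open(paths["manifest"], "w") as fh:
        json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths
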