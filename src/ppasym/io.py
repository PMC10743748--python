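"""Reading and writing the grid CSV dialect and cohort manifests.

Grid files are long-format CSV emulating a posterior-pole export: one row per
(eye, layer, cell) with columns

    subject_id, laterality, layer, row, col, thickness_um

(laterality in {R, L}, layer one of the ten labels, row/col 1-8, header row
required, UTF-8, comma-separated).  A file may hold one eye or a whole cohort.

A cohort manifest is a CSV listing eyes and where to find their grids:
columns ``subject_id, laterality, file`` plus optional metadata columns
(``age_years``, ``sex``, ...).  ``file`` paths are resolved relative to the
manifest's directory, and several manifest rows may point at the same long
file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .grid import (
    Cohort,
    EyeRecord,
    ThicknessGrid,
    validate_grid,
    validate_laterality,
    validate_layer,
)

__all__ = [
    "GRID_COLUMNS",
    "cohort_to_frame",
    "write_grid_csv",
    "read_grid_csv",
    "write_cohort",
    "load_cohort",
]

GRID_COLUMNS = ("subject_id", "laterality", "layer", "row", "col", "thickness_um")
MANIFEST_COLUMNS = ("subject_id", "laterality", "file")
_META_COLUMNS = ("age_years", "sex")


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format table of every cell of every grid of every eye."""
    records = []
    for eye in cohort:
        for layer in eye.layers:
            grid = eye.grids[layer]
            for addr, value in grid.as_cells().items():
                records.append(
                    (eye.subject_id, eye.laterality, layer, addr.row, addr.col, value)
                )
    return pd.DataFrame.from_records(records, columns=list(GRID_COLUMNS))


def write_grid_csv(cohort: Cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def _eyes_from_frame(df: pd.DataFrame, source: str) -> dict[tuple[str, str], EyeRecord]:
    missing = set(GRID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{source}: missing columns {sorted(missing)}")
    eyes: dict[tuple[str, str], EyeRecord] = {}
    grouped = df.groupby(["subject_id", "laterality", "layer"], sort=False)
    for (subject_id, laterality, layer), block in grouped:
        subject_id = str(subject_id)
        laterality = validate_laterality(laterality)
        layer = validate_layer(layer)
        cells = [
            ((int(r.row), int(r.col)), float(r.thickness_um))
            for r in block.itertuples(index=False)
        ]
        grid = ThicknessGrid.from_cells(subject_id, layer, laterality, cells)
        report = validate_grid(grid)
        if not report.ok:
            raise ValueError(
                f"{source}: invalid grid for {subject_id}/{layer}: "
                + "; ".join(report.errors[:5])
            )
        key = (subject_id, laterality)
        eye = eyes.setdefault(key, EyeRecord(subject_id, laterality))
        eye.add_grid(grid)
    return eyes


def read_grid_csv(path) -> list[EyeRecord]:
    """Read a long-format grid CSV into eye records (grouped by subject)."""
    path = Path(path)
    df = pd.read_csv(path)
    return list(_eyes_from_frame(df, str(path)).values())


def write_cohort(cohort: Cohort, directory, grids_name: str = "grids.csv") -> Path:
    """Write a cohort as one long grid CSV plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_grid_csv(cohort, directory / grids_name)
    rows = []
    for eye in cohort:
        row = {
            "subject_id": eye.subject_id,
            "laterality": eye.laterality,
            "file": grids_name,
        }
        for k in _META_COLUMNS:
            if k in eye.metadata:
                row[k] = eye.metadata[k]
        rows.append(row)
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_cohort(manifest_path, provenance: str = "") -> Cohort:
    """Load a cohort from a manifest, reading each referenced grid file once."""
    manifest_path = Path(manifest_path)
    mdf = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(mdf.columns)
    if missing:
        raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")

    cache: dict[Path, dict[tuple[str, str], EyeRecord]] = {}
    eyes: list[EyeRecord] = []
    for row in mdf.itertuples(index=False):
        file_path = (manifest_path.parent / str(row.file)).resolve()
        if file_path not in cache:
            df = pd.read_csv(file_path)
            cache[file_path] = _eyes_from_frame(df, str(file_path))
        key = (str(row.subject_id), validate_laterality(row.laterality))
        try:
            eye = cache[file_path][key]
        except KeyError:
            raise ValueError(
                f"{manifest_path}: eye {key[0]}/{key[1]} not found in {file_path}"
            ) from None
        for k in _META_COLUMNS:
            if hasattr(row, k) and pd.notna(getattr(row, k)):
                eye.metadata[k] = getattr(row, k)
        eyes.append(eye)
    return Cohort(eyes=eyes, provenance=provenance or f"loaded from {manifest_path}")
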