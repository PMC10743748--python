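"""Normative reference ranges for macular asymmetry and classification.

A normative database holds, for every layer and every corresponding cell pair
(keyed by the inferior cell), the central 95% reference range — the 2.5th and
97.5th percentiles — of the signed inferior-minus-superior thickness
difference in a healthy reference cohort.  A complete database over the ten
layers has 10 x 32 = 320 entries.  An observed asymmetry below the 2.5th or
above the 97.5th percentile of healthy eyes is flagged as likely pathological;
values exactly at a bound are within normal limits (the bounds themselves are
attained by healthy eyes).

Ranges are built from *signed* differences: thinning of a superior cell and
thinning of the mirror inferior cell move the statistic in opposite
directions, which is the information the two distinct percentile bounds
encode.

:class:`NormativeAsymmetryModel` is the scikit-learn-style front end
(``fit`` on a reference cohort, ``predict`` verdicts for new eyes);
:func:`build_normative_database` and :func:`classify_eye` are thin functional
wrappers around it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from . import __version__ as _pkg_version
from .grid import (
    INFERIOR_ADDRESSES,
    LAYERS,
    CellAddress,
    Cohort,
    EyeRecord,
    validate_layer,
)
from .stats import PercentileRange, cell_pair_differences, difference_matrix, percentile_range

__all__ = [
    "SCHEMA_VERSION",
    "NormativeEntry",
    "NormativeDatabase",
    "CellClassification",
    "NormativeAsymmetryModel",
    "build_normative_database",
    "classify_eye",
    "save_database",
    "load_database",
    "database_to_frame",
]

SCHEMA_VERSION = "1"

VERDICT_BELOW = "below_p2_5"
VERDICT_WITHIN = "within_normal"
VERDICT_ABOVE = "above_p97_5"


@dataclass(frozen=True)
class NormativeEntry:
    """Reference range for one (layer, corresponding-pair) combination.

    ``mean_diff``/``sd_diff`` of the reference differences are stored for
    auditability; classification uses only ``range``.
    """

    layer: str
    inferior_cell: CellAddress
    range: PercentileRange
    n_reference: int
    mean_diff: float
    sd_diff: float


@dataclass
class NormativeDatabase:
    """Collection of per-pair reference ranges plus provenance."""

    entries: dict[tuple[str, CellAddress], NormativeEntry] = field(default_factory=dict)
    provenance: str = ""
    schema_version: str = SCHEMA_VERSION

    def add(self, entry: NormativeEntry) -> None:
        key = (entry.layer, entry.inferior_cell)
        if key in self.entries:
            raise ValueError(f"duplicate normative entry for {key[0]} cell {key[1]}")
        self.entries[key] = entry

    def lookup(self, layer: str, inferior_cell: CellAddress) -> NormativeEntry:
        key = (validate_layer(layer), CellAddress(*inferior_cell))
        try:
            return self.entries[key]
        except KeyError:
            raise KeyError(
                f"no normative entry for layer {key[0]}, inferior cell {key[1]}"
            ) from None

    def layers(self) -> tuple[str, ...]:
        present = {layer for layer, _ in self.entries}
        return tuple(l for l in LAYERS if l in present)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NormativeDatabase):
            return NotImplemented
        return (
            self.schema_version == other.schema_version
            and self.provenance == other.provenance
            and self.entries == other.entries
        )


@dataclass(frozen=True)
class CellClassification:
    """Verdict for one observed pair asymmetry against the reference range."""

    layer: str
    inferior_cell: CellAddress
    observed_diff: float
    verdict: str

    @property
    def out_of_range(self) -> bool:
        return self.verdict != VERDICT_WITHIN


class NormativeAsymmetryModel(BaseEstimator):
    """Normative-range model for superior-inferior macular asymmetry.

    Fitting computes, for every requested layer and each of the 32
    corresponding cell pairs, the empirical central 95% range (2.5th/97.5th
    percentiles, linear rank interpolation) of the signed inferior-minus-
    superior differences across the reference cohort.  Prediction classifies
    each pair of a new eye as below, within, or above that range; bounds are
    inclusive.

    Parameters
    ----------
    layers : sequence of str, optional
        Layers to include; default all ten (RNFL ... RETINA).

    Attributes
    ----------
    database_ : NormativeDatabase
        The fitted per-pair reference ranges.
    n_eyes_ : int
        Number of reference eyes.
    layers_ : tuple of str
        Layers actually fitted, in canonical order.
    """

    def __init__(self, layers=None):
        self.layers = layers

    def fit(self, cohort: Cohort, y=None) -> "NormativeAsymmetryModel":
        """Build the reference ranges from a healthy cohort."""
        if not isinstance(cohort, Cohort):
            raise TypeError("fit expects a Cohort")
        if len(cohort) < 2:
            raise ValueError("reference cohort must contain at least 2 eyes")
        layers = tuple(
            validate_layer(l) for l in (self.layers if self.layers is not None else LAYERS)
        )
        missing: list[str] = []
        for layer in layers:
            for eye in cohort:
                if layer not in eye.grids:
                    missing.append(f"{eye.subject_id}: {layer}")
        if missing:
            raise ValueError(
                "incomplete layer coverage in reference cohort: "
                + "; ".join(missing[:10])
                + ("; ..." if len(missing) > 10 else "")
            )
        db = NormativeDatabase(
            provenance=f"reference cohort of {len(cohort)} eyes"
            + (f" ({cohort.provenance})" if cohort.provenance else ""),
        )
        for layer in layers:
            diffs = difference_matrix(cohort, layer)  # (n_eyes, 32)
            for j, addr in enumerate(INFERIOR_ADDRESSES):
                col = diffs[:, j]
                db.add(
                    NormativeEntry(
                        layer=layer,
                        inferior_cell=addr,
                        range=percentile_range(col),
                        n_reference=col.size,
                        mean_diff=float(col.mean()),
                        sd_diff=float(col.std(ddof=1)),
                    )
                )
        self.database_ = db
        self.n_eyes_ = len(cohort)
        self.layers_ = layers
        return self

    def predict(self, eye: EyeRecord) -> list[CellClassification]:
        """Classify every available (layer, pair) of one eye."""
        self._check_fitted()
        covered = [l for l in self.layers_ if l in eye.grids]
        return classify_eye(eye, self.database_, layers=covered)

    def _check_fitted(self) -> None:
        if not hasattr(self, "database_"):
            raise RuntimeError("model is not fitted; call fit(cohort) first")


def classify_verdict(observed: float, rng: PercentileRange) -> str:
    if observed < rng.p2_5:
        return VERDICT_BELOW
    if observed > rng.p97_5:
        return VERDICT_ABOVE
    return VERDICT_WITHIN


def build_normative_database(cohort: Cohort, layers=None) -> NormativeDatabase:
    """Build a normative database from a reference cohort (all layers by default)."""
    return NormativeAsymmetryModel(layers=layers).fit(cohort).database_


def classify_eye(
    eye: EyeRecord, db: NormativeDatabase, layers=None
) -> list[CellClassification]:
    """Classify one eye's pair asymmetries against a normative database.

    By default covers every layer the eye carries; a covered layer missing
    from the database is an error (silent partial coverage would hide
    pathology).  Pass ``layers`` to restrict coverage explicitly.
    """
    if layers is None:
        layers = eye.layers
    out: list[CellClassification] = []
    for layer in (validate_layer(l) for l in layers):
        diffs = cell_pair_differences(eye, layer)
        for addr, observed in diffs.items():
            entry = db.lookup(layer, addr)
            out.append(
                CellClassification(
                    layer=layer,
                    inferior_cell=addr,
                    observed_diff=float(observed),
                    verdict=classify_verdict(float(observed), entry.range),
                )
            )
    return out


def save_database(db: NormativeDatabase, destination) -> None:
    """Write a normative database as JSON (schema_version, provenance, entries)."""
    payload = {
        "schema_version": db.schema_version,
        "provenance": db.provenance,
        "generator": f"ppasym {_pkg_version}",
        "sign_convention": "inferior_minus_superior",
        "entries": [
            {
                "layer": e.layer,
                "inf_row": e.inferior_cell.row,
                "inf_col": e.inferior_cell.col,
                "p2_5_um": e.range.p2_5,
                "p97_5_um": e.range.p97_5,
                "n_reference": e.n_reference,
                "mean_diff_um": e.mean_diff,
                "sd_diff_um": e.sd_diff,
            }
            for e in db.entries.values()
        ],
    }
    Path(destination).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_database(source) -> NormativeDatabase:
    """Load and validate a JSON normative database.

    Rejects schema-version mismatches, malformed entries, and duplicate
    (layer, cell) keys.  An empty entries list loads with a warning.
    """
    try:
        payload = json.loads(Path(source).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed normative database file {source}: {exc}") from exc
    if not isinstance(payload, dict) or "entries" not in payload:
        raise ValueError(f"malformed normative database file {source}: no entries key")
    version = str(payload.get("schema_version", ""))
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported normative database schema_version {version!r}; "
            f"expected {SCHEMA_VERSION!r}"
        )
    db = NormativeDatabase(
        provenance=str(payload.get("provenance", "")), schema_version=version
    )
    required = {"layer", "inf_row", "inf_col", "p2_5_um", "p97_5_um",
                "n_reference", "mean_diff_um", "sd_diff_um"}
    for i, raw in enumerate(payload["entries"]):
        missing = required - set(raw)
        if missing:
            raise ValueError(f"entry {i} is missing fields: {sorted(missing)}")
        entry = NormativeEntry(
            layer=validate_layer(raw["layer"]),
            inferior_cell=CellAddress(int(raw["inf_row"]), int(raw["inf_col"])),
            range=PercentileRange(float(raw["p2_5_um"]), float(raw["p97_5_um"])),
            n_reference=int(raw["n_reference"]),
            mean_diff=float(raw["mean_diff_um"]),
            sd_diff=float(raw["sd_diff_um"]),
        )
        if entry.inferior_cell.row > 4:
            raise ValueError(
                f"entry {i}: cell {entry.inferior_cell} is not in the inferior hemisphere"
            )
        db.add(entry)  # raises on duplicate keys
    if not db.entries:
        warnings.warn(f"normative database {source} contains no entries", stacklevel=2)
    return db


def database_to_frame(db: NormativeDatabase) -> "pandas.DataFrame":  # noqa: F821
    """Tabular (CSV-ready) view of a database, same columns as the JSON entries."""
    import pandas as pd

    entries = sorted(
        db.entries.values(), key=lambda e: (LAYERS.index(e.layer), e.inferior_cell)
    )
    return pd.DataFrame(
        {
            "layer": [e.layer for e in entries],
            "inf_row": [e.inferior_cell.row for e in entries],
            "inf_col": [e.inferior_cell.col for e in entries],
            "p2_5_um": [e.range.p2_5 for e in entries],
            "p97_5_um": [e.range.p97_5 for e in entries],
            "n_reference": [e.n_reference for e in entries],
            "mean_diff_um": [e.mean_diff for e in entries],
            "sd_diff_um": [e.sd_diff for e in entries],
        }
    )
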