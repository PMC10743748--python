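"""Data model for the 8x8 posterior pole thickness grid.

The Spectralis posterior pole algorithm (PPA) maps macular thickness onto a
grid of 64 cells (8 rows x 8 columns, each 3 degrees x 3 degrees) aligned to
the fovea-disk axis.  Cells are numbered from inferior to superior (rows) and
from temporal to nasal (columns), so cell 1.1 is the most inferior-temporal
cell and cell 8.8 the most superior-nasal — in both right and left eyes
(specular nomenclature).  Because the nomenclature is specular, anatomically
homologous cells share the same address across laterality and no data
remapping is ever needed; rendering left eyes "in right-eye format" is purely
a display-time column mirror (see :func:`display_orientation`).

Thickness values are stored in microns as floats: device exports are integer
microns, but cohort averaging produces fractions and rounding would leak into
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np

__all__ = [
    "LAYERS",
    "LATERALITIES",
    "GRID_SIZE",
    "CellAddress",
    "ALL_ADDRESSES",
    "INFERIOR_ADDRESSES",
    "SUPERIOR_ADDRESSES",
    "ThicknessGrid",
    "EyeRecord",
    "Cohort",
    "ValidationReport",
    "corresponding_cell",
    "hemisphere_of",
    "display_orientation",
    "validate_grid",
    "validate_layer",
    "validate_laterality",
]

#: The ten segmented macular layers, in fixed reporting order: the seven
#: individually segmented layers (inner to outer) followed by the three joint
#: segmentations (inner retina = RNFL..ONL, outer retina = photoreceptors+RPE,
#: complete retina).
LAYERS: tuple[str, ...] = (
    "RNFL", "GCL", "IPL", "INL", "OPL", "ONL", "RPE", "INNER", "OUTER", "RETINA",
)

#: Eye laterality codes: "R" (right) and "L" (left).
LATERALITIES: tuple[str, str] = ("R", "L")

GRID_SIZE = 8

_LATERALITY_ALIASES = {
    "R": "R", "L": "L", "RIGHT": "R", "LEFT": "L", "OD": "R", "OS": "L",
}


class CellAddress(NamedTuple):
    """Grid cell address in the device's 1-based ``row.col`` nomenclature.

    ``row`` runs 1 (most inferior) to 8 (most superior); ``col`` runs
    1 (most temporal) to 8 (most nasal).
    """

    row: int
    col: int

    def __str__(self) -> str:  # e.g. "3.7", matching the device's labels
        return f"{self.row}.{self.col}"


def _check_address(address: CellAddress | tuple[int, int]) -> CellAddress:
    row, col = address
    if not (1 <= row <= GRID_SIZE and 1 <= col <= GRID_SIZE):
        raise ValueError(
            f"invalid cell address ({row},{col}): row and col must be in 1..{GRID_SIZE}"
        )
    return CellAddress(int(row), int(col))


#: All 64 addresses in row-major order from row 1 (inferior) upward.
ALL_ADDRESSES: tuple[CellAddress, ...] = tuple(
    CellAddress(r, c) for r in range(1, GRID_SIZE + 1) for c in range(1, GRID_SIZE + 1)
)

#: The 32 inferior-hemisphere addresses (rows 1-4), row-major.
INFERIOR_ADDRESSES: tuple[CellAddress, ...] = tuple(
    a for a in ALL_ADDRESSES if a.row <= GRID_SIZE // 2
)

#: The 32 superior-hemisphere addresses (rows 5-8), row-major.
SUPERIOR_ADDRESSES: tuple[CellAddress, ...] = tuple(
    a for a in ALL_ADDRESSES if a.row > GRID_SIZE // 2
)


def corresponding_cell(address: CellAddress | tuple[int, int]) -> CellAddress:
    """Return the cell mirrored across the horizontal midline.

    Corresponding cells are the pair compared by the asymmetry analysis:
    row ``r`` maps to row ``9 - r`` in the same column (cell 1.1 pairs with
    cell 8.1).  The map is an involution and always crosses the midline.
    """
    addr = _check_address(address)
    return CellAddress(GRID_SIZE + 1 - addr.row, addr.col)


def hemisphere_of(address: CellAddress | tuple[int, int]) -> str:
    """Return ``"inferior"`` (rows 1-4) or ``"superior"`` (rows 5-8)."""
    addr = _check_address(address)
    return "inferior" if addr.row <= GRID_SIZE // 2 else "superior"


def validate_layer(layer: str) -> str:
    """Canonicalise and validate a layer label against the ten admissible ones."""
    lab = str(layer).strip().upper()
    if lab not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {', '.join(LAYERS)}")
    return lab


def validate_laterality(laterality: str) -> str:
    """Canonicalise a laterality flag to ``"R"`` or ``"L"``."""
    lab = str(laterality).strip().upper()
    if lab not in _LATERALITY_ALIASES:
        raise ValueError(f"unknown laterality {laterality!r}; expected R or L")
    return _LATERALITY_ALIASES[lab]


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a structural validation; ``ok`` iff no errors were found."""

    errors: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            raise ValueError("grid validation failed: " + "; ".join(self.errors))


@dataclass
class ThicknessGrid:
    """One eye, one layer: 64 cell thickness values in microns.

    ``values`` is an 8x8 float array indexed ``[row - 1, col - 1]``, i.e.
    row index 0 is the most inferior row.  Use :meth:`from_cells` to build a
    grid from an address->value mapping with completeness checking.
    """

    subject_id: str
    layer: str
    laterality: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.layer = validate_layer(self.layer)
        self.laterality = validate_laterality(self.laterality)
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(
                f"grid values must be {GRID_SIZE}x{GRID_SIZE}, got shape {arr.shape}"
            )
        self.values = arr

    @classmethod
    def from_cells(
        cls,
        subject_id: str,
        layer: str,
        laterality: str,
        cells: Mapping[tuple[int, int], float] | Iterable[tuple[tuple[int, int], float]],
    ) -> "ThicknessGrid":
        """Build a grid from an address->thickness mapping.

        Rejects duplicate or invalid addresses and incomplete grids: the
        acquisition pipeline excludes artefactual scans rather than repairing
        them, so no imputation of missing cells is performed.
        """
        items = cells.items() if isinstance(cells, Mapping) else cells
        arr = np.full((GRID_SIZE, GRID_SIZE), np.nan)
        seen: set[CellAddress] = set()
        for address, value in items:
            addr = _check_address(address)
            if addr in seen:
                raise ValueError(f"duplicate cell address {addr}")
            seen.add(addr)
            arr[addr.row - 1, addr.col - 1] = float(value)
        missing = [a for a in ALL_ADDRESSES if a not in seen]
        if missing:
            raise ValueError(
                f"incomplete grid: missing {len(missing)} cells "
                f"({', '.join(str(a) for a in missing[:8])}"
                + (", ..." if len(missing) > 8 else "") + ")"
            )
        return cls(subject_id, layer, laterality, arr)

    def value_at(self, address: CellAddress | tuple[int, int]) -> float:
        addr = _check_address(address)
        return float(self.values[addr.row - 1, addr.col - 1])

    def as_cells(self) -> dict[CellAddress, float]:
        return {a: float(self.values[a.row - 1, a.col - 1]) for a in ALL_ADDRESSES}


def validate_grid(grid: ThicknessGrid) -> ValidationReport:
    """Check a grid against its invariants (complete, finite, non-negative).

    Returns a report rather than raising, so batch loaders can list every
    offending cell of every eye before aborting.
    """
    errors: list[str] = []
    vals = np.asarray(grid.values, dtype=float)
    if vals.shape != (GRID_SIZE, GRID_SIZE):
        return ValidationReport((f"expected 8x8 values, got shape {vals.shape}",))
    for a in ALL_ADDRESSES:
        v = vals[a.row - 1, a.col - 1]
        if not np.isfinite(v):
            errors.append(f"cell {a}: non-finite value {v}")
        elif v < 0:
            errors.append(f"cell {a}: negative thickness {v} um")
    return ValidationReport(tuple(errors))


def display_orientation(grid: ThicknessGrid) -> np.ndarray:
    """Return the 8x8 value array oriented for right-eye-format rendering.

    Right eyes render in storage order.  For left eyes the horizontal axis is
    mirrored so that the plotted map appears as if the eye were a right eye,
    matching the device's convention.  This is a display transform only: the
    specular nomenclature already makes identically addressed cells
    anatomically homologous, so stored addresses and all statistics are
    unaffected.
    """
    if grid.laterality == "R":
        return np.array(grid.values, copy=True)
    return np.array(grid.values[:, ::-1], copy=True)


@dataclass
class EyeRecord:
    """All available layer grids for one eye, plus optional metadata."""

    subject_id: str
    laterality: str
    grids: dict[str, ThicknessGrid] = field(default_factory=dict)
    metadata: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.laterality = validate_laterality(self.laterality)
        for layer, grid in self.grids.items():
            self._check_grid(layer, grid)

    def _check_grid(self, layer: str, grid: ThicknessGrid) -> None:
        if grid.layer != validate_layer(layer):
            raise ValueError(
                f"grid registered under layer {layer!r} is labelled {grid.layer!r}"
            )
        if grid.subject_id != self.subject_id or grid.laterality != self.laterality:
            raise ValueError(
                f"grid for {grid.subject_id}/{grid.laterality} does not belong to "
                f"eye {self.subject_id}/{self.laterality}"
            )

    def add_grid(self, grid: ThicknessGrid) -> None:
        if grid.layer in self.grids:
            raise ValueError(f"eye {self.subject_id} already has a {grid.layer} grid")
        self._check_grid(grid.layer, grid)
        self.grids[grid.layer] = grid

    def grid_for(self, layer: str) -> ThicknessGrid:
        layer = validate_layer(layer)
        try:
            return self.grids[layer]
        except KeyError:
            raise KeyError(
                f"eye {self.subject_id} has no grid for layer {layer}"
            ) from None

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(l for l in LAYERS if l in self.grids)


@dataclass
class Cohort:
    """An ordered collection of eyes, one per subject."""

    eyes: list[EyeRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for eye in self.eyes:
            if eye.subject_id in seen:
                raise ValueError(
                    f"cohort contains more than one eye for subject {eye.subject_id!r}; "
                    "only one eye per subject is admissible"
                )
            seen.add(eye.subject_id)

    def __len__(self) -> int:
        return len(self.eyes)

    def __iter__(self) -> Iterator[EyeRecord]:
        return iter(self.eyes)

    def layers_present(self) -> tuple[str, ...]:
        """Layers available in every eye of the cohort."""
        if not self.eyes:
            return ()
        common = set(LAYERS)
        for eye in self.eyes:
            common &= set(eye.layers)
        return tuple(l for l in LAYERS if l in common)

    def require_layer(self, layer: str) -> None:
        layer = validate_layer(layer)
        missing = [e.subject_id for e in self.eyes if layer not in e.grids]
        if missing:
            raise ValueError(
                f"layer {layer} missing for {len(missing)} eye(s): "
                + ", ".join(missing[:5]) + (", ..." if len(missing) > 5 else "")
            )
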