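"""Asymmetry map rendering.

Two map styles are produced:

* a cohort-level significance-masked *deviation heatmap*: for each
  corresponding pair with mean inferior-minus-superior difference ``d``, half
  the difference is plotted in each member of the pair (``+d/2`` at the
  inferior cell, ``-d/2`` at the superior one) when the pair's paired t-test
  is significant; non-significant pairs are drawn black.  Red encodes
  thickening, blue thinning, and the horizontal midline is drawn green.  The
  half-difference is attributed symmetrically so each hemisphere shows its own
  excess relative to the pair midpoint, and each map sums to exactly zero over
  every pair.

* a per-eye *device-style* grayscale map of the absolute pair difference,
  linearly mapped on 0-30 um and saturating at 30 um — the ceiling the
  instrument's own asymmetry display can represent.

Left-eye data are rendered in right-eye format (display-time column mirror);
the underlying arrays and statistics are never remapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .grid import (
    GRID_SIZE,
    INFERIOR_ADDRESSES,
    CellAddress,
    EyeRecord,
    corresponding_cell,
    display_orientation,
    validate_layer,
)
from .stats import PairDifferenceSummary, cell_pair_differences

__all__ = [
    "DEVICE_CLAMP_UM",
    "DeviationMap",
    "deviation_map",
    "heatmap_rgba",
    "render_heatmap",
    "device_asymmetry_array",
    "device_style_map",
]

#: The instrument's asymmetry display saturates at this absolute difference.
DEVICE_CLAMP_UM = 30.0

_HALF = GRID_SIZE // 2


@dataclass(frozen=True)
class DeviationMap:
    """Signed half-difference per cell plus a significance mask.

    ``values[r-1, c-1]`` is the deviation of cell (r, c) from its pair
    midpoint; it is antisymmetric across the midline.  ``mask`` is True where
    the pair is significant; it is symmetric across the midline (a pair is
    significant as a unit).
    """

    layer: str
    values: np.ndarray  # (8, 8) float, microns
    mask: np.ndarray  # (8, 8) bool


def deviation_map(summaries: Sequence[PairDifferenceSummary]) -> DeviationMap:
    """Build the half-difference deviation map from 32 pair summaries.

    For a pair with mean difference ``d`` (inferior minus superior):
    ``+d/2`` at the inferior cell, ``-d/2`` at the superior cell.
    """
    if len(summaries) != len(INFERIOR_ADDRESSES):
        raise ValueError(
            f"expected {len(INFERIOR_ADDRESSES)} pair summaries, got {len(summaries)}"
        )
    layers = {s.layer for s in summaries}
    if len(layers) != 1:
        raise ValueError(f"summaries mix layers: {sorted(layers)}")
    covered = {s.inferior_cell for s in summaries}
    missing = [a for a in INFERIOR_ADDRESSES if a not in covered]
    if missing:
        raise ValueError(f"summaries missing inferior cells: {missing[:5]}")

    values = np.zeros((GRID_SIZE, GRID_SIZE))
    mask = np.zeros((GRID_SIZE, GRID_SIZE), dtype=bool)
    for s in summaries:
        inf, sup = s.inferior_cell, s.superior_cell
        values[inf.row - 1, inf.col - 1] = +0.5 * s.mean_diff
        values[sup.row - 1, sup.col - 1] = -0.5 * s.mean_diff
        mask[inf.row - 1, inf.col - 1] = s.significant
        mask[sup.row - 1, sup.col - 1] = s.significant
    return DeviationMap(layer=next(iter(layers)), values=values, mask=mask)


def heatmap_rgba(
    dmap: DeviationMap, laterality: str = "R", vlim: float | None = None
) -> np.ndarray:
    """Deterministic (8, 8, 4) RGBA array for a deviation map.

    Positive deviations red, negative blue (diverging colormap symmetric
    about zero so equal magnitudes have equal saturation); non-significant
    cells black.  Row index 0 is the most inferior row; left eyes are
    column-mirrored into right-eye format.
    """
    vals = np.array(dmap.values, copy=True)
    mask = np.array(dmap.mask, copy=True)
    if laterality in ("L", "left", "LEFT", "OS"):
        vals = vals[:, ::-1]
        mask = mask[:, ::-1]
    if vlim is None:
        vlim = float(np.max(np.abs(vals[mask]))) if mask.any() else 1.0
        vlim = vlim or 1.0
    cmap = plt.get_cmap("bwr").copy()
    cmap.set_bad(color="black")
    norm = matplotlib.colors.Normalize(vmin=-vlim, vmax=vlim)
    shown = np.ma.masked_array(vals, mask=~mask)
    return cmap(norm(shown))


def render_heatmap(
    dmap: DeviationMap,
    destination,
    laterality: str = "R",
    vlim: float | None = None,
    overlay: bool = False,
    title: str | None = None,
) -> None:
    """Write the significance-masked half-difference heatmap to PNG/SVG.

    Superior rows are drawn at the top, the horizontal midline in green.
    ``overlay=True`` prints the deviation value (microns) in each significant
    cell.
    """
    rgba = heatmap_rgba(dmap, laterality=laterality, vlim=vlim)
    vals = dmap.values if laterality not in ("L", "left", "LEFT", "OS") else dmap.values[:, ::-1]
    mask = dmap.mask if laterality not in ("L", "left", "LEFT", "OS") else dmap.mask[:, ::-1]

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    # origin="lower" puts row 1 (inferior) at the bottom, as on the device
    ax.imshow(rgba, origin="lower", extent=(0.5, 8.5, 0.5, 8.5), interpolation="nearest")
    ax.axhline(y=_HALF + 0.5, color="green", linewidth=3)
    if overlay:
        for r in range(GRID_SIZE):
            for c in range(GRID_SIZE):
                if mask[r, c]:
                    ax.text(
                        c + 1, r + 1, f"{vals[r, c]:+.1f}",
                        ha="center", va="center", fontsize=6, color="black",
                    )
    ax.set_xticks(range(1, 9))
    ax.set_yticks(range(1, 9))
    ax.set_xlabel("column (temporal to nasal, right-eye format)")
    ax.set_ylabel("row (inferior to superior)")
    ax.set_title(title if title is not None else f"{dmap.layer} asymmetry (half mean difference, um)")
    fig.tight_layout()
    fig.savefig(destination, dpi=150)
    plt.close(fig)


def device_asymmetry_array(eye: EyeRecord, layer: str) -> np.ndarray:
    """Absolute pair difference per cell, clamped at 30 um.

    Both members of a pair carry the same magnitude, emulating the
    instrument's per-eye asymmetry display.
    """
    layer = validate_layer(layer)
    diffs = cell_pair_differences(eye, layer)
    arr = np.zeros((GRID_SIZE, GRID_SIZE))
    for a, d in diffs.items():
        mag = min(abs(float(d)), DEVICE_CLAMP_UM)
        b = corresponding_cell(a)
        arr[a.row - 1, a.col - 1] = mag
        arr[b.row - 1, b.col - 1] = mag
    return arr


def device_style_map(eye: EyeRecord, layer: str, destination) -> np.ndarray:
    """Write the per-eye grayscale asymmetry map; returns the clamped array.

    Linear 0-30 um ramp, white (symmetric) to black (>= 30 um difference).
    """
    arr = device_asymmetry_array(eye, layer)
    grid = eye.grid_for(layer)
    shown = arr if eye.laterality == "R" else arr[:, ::-1]
    # reuse display_orientation semantics for consistency with heatmaps
    assert shown.shape == display_orientation(grid).shape

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    ax.imshow(
        shown, origin="lower", extent=(0.5, 8.5, 0.5, 8.5),
        cmap="gray_r", vmin=0.0, vmax=DEVICE_CLAMP_UM, interpolation="nearest",
    )
    ax.axhline(y=_HALF + 0.5, color="green", linewidth=2)
    ax.set_xticks(range(1, 9))
    ax.set_yticks(range(1, 9))
    ax.set_title(f"{layer} |inferior - superior| (clamped at {DEVICE_CLAMP_UM:.0f} um)")
    fig.tight_layout()
    fig.savefig(destination, dpi=150)
    plt.close(fig)
    return arr
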