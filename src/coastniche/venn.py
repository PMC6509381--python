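"""Venn four-set decomposition of habitat change.

Binary habitat maps under the current state (HCUR) and the three futures
(HCLC climate-only, HSLR sea-level-rise-only, HCCS combined) form a four-set
Venn diagram. Change is judged between HCUR and HCCS: unchanged cells are
HCCS intersect HCUR, gains HCCS minus HCUR, losses HCUR minus HCCS. Each
changed cell is then attributed to one of four effects by where it sits
relative to the single-driver futures:

gain (cell in HCCS, not HCUR):
  shared    — gained under both single scenarios (in HCLC and HSLR);
  pure_clc  — gained under climate change alone (in HCLC only);
  pure_slr  — gained under sea-level rise alone (in HSLR only);
  coupling  — gained under neither single scenario: only the combination
              produces it.

loss (cell in HCUR, not HCCS) under the default ``as_printed`` convention,
which follows the published equations literally (losses classified by the
cell's *retention* in the single-driver futures):
  shared    — still suitable under both HCLC and HSLR;
  pure_clc  — still suitable under HCLC (and not the above);
  pure_slr  — still suitable under HSLR (and not the above);
  coupling  — suitable under neither single scenario.

The alternative ``symmetric`` convention mirrors the gain logic (losses
classified by loss under the single scenarios). The two conventions label the
same four cell sets and differ only by the permutation
shared <-> coupling, pure_clc <-> pure_slr.

Cells inundated (masked) under a scenario count as unsuitable there —
inundation is genuine habitat loss, not missing data; only cells masked under
every scenario are nodata.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec, write_ascii_grid, read_ascii_grid

#: Integer codes of the decomposition map.
LABELS = {
    "absent": 0,
    "unchanged": 1,
    "p_clc_gain": 2,
    "p_slr_gain": 3,
    "s_ics_gain": 4,
    "c_ics_gain": 5,
    "p_clc_loss": 6,
    "p_slr_loss": 7,
    "s_ics_loss": 8,
    "c_ics_loss": 9,
}
NODATA_CODE = -1
GAIN_LABELS = ("p_clc_gain", "p_slr_gain", "s_ics_gain", "c_ics_gain")
LOSS_LABELS = ("p_clc_loss", "p_slr_loss", "s_ics_loss", "c_ics_loss")

#: Display colours for exported legends (hex), one per label.
LABEL_COLORS = {
    "absent": "#f0f0f0", "unchanged": "#999999",
    "p_clc_gain": "#1b9e77", "p_slr_gain": "#66c2a5",
    "s_ics_gain": "#a6d854", "c_ics_gain": "#e6f5c9",
    "p_clc_loss": "#d95f02", "p_slr_loss": "#fc8d62",
    "s_ics_loss": "#fdcdac", "c_ics_loss": "#7570b3",
}


@dataclass
class BinaryHabitatMap:
    """0/1 suitability on a grid; nodata carried as a boolean mask."""

    grid: GridSpec
    values: np.ndarray
    nodata: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.values.shape != self.grid.shape or self.nodata.shape != self.grid.shape:
            raise ValueError("habitat map shape does not match grid")

    def as_set(self) -> np.ndarray:
        """Suitable-cell indicator with masked cells counting as unsuitable."""
        return (self.values == 1) & ~self.nodata


def binarize(suitability: np.ndarray, threshold: float,
             grid: GridSpec, nodata: np.ndarray | None = None) -> BinaryHabitatMap:
    """Suitable where cloglog suitability >= threshold; nodata propagated."""
    if not 0 <= threshold <= 1 + 1e-12:
        raise ValueError("threshold must lie in [0, 1]")
    if nodata is None:
        nodata = grid.nodata_mask
    nodata = np.asarray(nodata, dtype=bool) | ~np.isfinite(np.asarray(suitability, dtype=float))
    values = (np.nan_to_num(np.asarray(suitability, dtype=float)) >= threshold) & ~nodata
    return BinaryHabitatMap(grid, values.astype(np.uint8), nodata)


@dataclass
class ScenarioHabitats:
    HCUR: BinaryHabitatMap
    HCLC: BinaryHabitatMap
    HSLR: BinaryHabitatMap
    HCCS: BinaryHabitatMap

    def __post_init__(self) -> None:
        g = self.HCUR.grid
        for name in ("HCLC", "HSLR", "HCCS"):
            if getattr(self, name).grid.shape != g.shape:
                raise ValueError(f"{name} grid differs from HCUR")

    @property
    def common_nodata(self) -> np.ndarray:
        """Cells invalid under every scenario (never land in any of the four)."""
        return (self.HCUR.nodata & self.HCLC.nodata
                & self.HSLR.nodata & self.HCCS.nodata)


def changed_sets(sh: ScenarioHabitats) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(unchanged, gain, loss) boolean cell sets between HCUR and HCCS."""
    cur, ccs = sh.HCUR.as_set(), sh.HCCS.as_set()
    unchanged = ccs & cur
    gain = ccs & ~cur
    loss = cur & ~ccs
    return unchanged, gain, loss


def attribute_gain(sh: ScenarioHabitats) -> dict[str, np.ndarray]:
    """Partition the gained cells among the four effects (see module doc)."""
    cur = sh.HCUR.as_set()
    clc_gain = sh.HCLC.as_set() & ~cur
    slr_gain = sh.HSLR.as_set() & ~cur
    _, gain, _ = changed_sets(sh)
    shared = gain & clc_gain & slr_gain
    pure_clc = gain & clc_gain & ~shared
    pure_slr = gain & slr_gain & ~shared
    coupling = gain & ~(shared | pure_clc | pure_slr)
    return {
        "p_clc_gain": pure_clc,
        "p_slr_gain": pure_slr,
        "s_ics_gain": shared,
        "c_ics_gain": coupling,
    }


def attribute_loss(sh: ScenarioHabitats, convention: str = "as_printed") -> dict[str, np.ndarray]:
    """Partition the lost cells among the four effects.

    ``as_printed`` classifies a lost cell by its membership in the
    single-scenario habitat sets (retention); ``symmetric`` by its loss under
    the single scenarios, mirroring the gain logic. Identical four regions,
    permuted labels.
    """
    cur = sh.HCUR.as_set()
    _, _, loss = changed_sets(sh)
    if convention == "as_printed":
        clc_keep = sh.HCLC.as_set() & cur
        slr_keep = sh.HSLR.as_set() & cur
        shared = loss & clc_keep & slr_keep
        pure_clc = loss & clc_keep & ~shared
        pure_slr = loss & slr_keep & ~shared
        coupling = loss & ~(shared | pure_clc | pure_slr)
    elif convention == "symmetric":
        clc_loss = cur & ~sh.HCLC.as_set()
        slr_loss = cur & ~sh.HSLR.as_set()
        shared = loss & clc_loss & slr_loss
        pure_clc = loss & clc_loss & ~shared
        pure_slr = loss & slr_loss & ~shared
        coupling = loss & ~(shared | pure_clc | pure_slr)
    else:
        raise ValueError(f"unknown loss convention {convention!r}")
    return {
        "p_clc_loss": pure_clc,
        "p_slr_loss": pure_slr,
        "s_ics_loss": shared,
        "c_ics_loss": coupling,
    }


@dataclass
class DecompositionMap:
    grid: GridSpec
    codes: np.ndarray           # int codes per LABELS, NODATA_CODE where invalid
    convention: str

    def count(self, label: str) -> int:
        return int((self.codes == LABELS[label]).sum())

    def label_counts(self) -> dict[str, int]:
        return {label: self.count(label) for label in LABELS}


def decompose(sh: ScenarioHabitats, convention: str = "as_printed") -> DecompositionMap:
    """Label every cell: absent / unchanged / one of the eight change labels.

    Cells masked under every scenario are nodata; all others are labelled
    exactly once.
    """
    unchanged, gain, loss = changed_sets(sh)
    codes = np.full(sh.HCUR.grid.shape, LABELS["absent"], dtype=np.int16)
    codes[unchanged] = LABELS["unchanged"]
    for label, cells in attribute_gain(sh).items():
        codes[cells] = LABELS[label]
    for label, cells in attribute_loss(sh, convention).items():
        codes[cells] = LABELS[label]
    codes[sh.common_nodata] = NODATA_CODE
    return DecompositionMap(sh.HCUR.grid, codes, convention)


def _round_half_up(value: float, decimals: int = 2) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("1." + "0" * decimals),
                                               rounding=ROUND_HALF_UP))


@dataclass
class AreaTable:
    """Changed-habitat areas (km^2) and percentages per effect class.

    One row per direction (gain/loss) with the four component areas, their
    percentage of that direction's changed total (half-up, 2 decimals) and
    the total. ``zero_total_flags`` lists directions whose changed total was
    zero (percentages reported as 0).
    """

    table: pd.DataFrame
    zero_total_flags: list[str]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def area_table(decomp: DecompositionMap, cell_size: float | None = None) -> AreaTable:
    """Accounting table of the decomposition: area = cell count x cell area."""
    if cell_size is None:
        cell_size = decomp.grid.cell_size
    cell_area = cell_size ** 2
    rows = []
    flags: list[str] = []
    for direction, labels in (("gain", GAIN_LABELS), ("loss", LOSS_LABELS)):
        areas = {lab: decomp.count(lab) * cell_area for lab in labels}
        total = sum(areas.values())
        row: dict[str, float | str] = {"direction": direction}
        for lab in labels:
            short = lab.rsplit("_", 1)[0]  # p_clc, p_slr, s_ics, c_ics
            row[f"H_{short}"] = areas[lab]
            if total > 0:
                row[f"H_{short}_pct"] = _round_half_up(100.0 * areas[lab] / total)
            else:
                row[f"H_{short}_pct"] = 0.0
        row["H_changed"] = total
        row["H_changed_pct"] = 100.0 if total > 0 else 0.0
        if total == 0:
            flags.append(direction)
        rows.append(row)
    return AreaTable(pd.DataFrame(rows), flags)


def export_map(decomp: DecompositionMap, raster_path: str | Path,
               legend_path: str | Path) -> None:
    """Write the coded decomposition raster (.asc) and a CSV legend of the
    labels present."""
    grid = decomp.grid.copy()
    grid.nodata_mask = decomp.codes == NODATA_CODE
    write_ascii_grid(raster_path, decomp.codes.astype(float), grid,
                     nodata=float(NODATA_CODE), fmt="%d")
    present = np.unique(decomp.codes[decomp.codes != NODATA_CODE])
    code_to_label = {v: k for k, v in LABELS.items()}
    legend = pd.DataFrame({
        "code": present,
        "label": [code_to_label[c] for c in present],
        "color": [LABEL_COLORS[code_to_label[c]] for c in present],
    })
    legend.to_csv(legend_path, index=False)


def import_map(raster_path: str | Path, convention: str = "as_printed") -> DecompositionMap:
    """Read a coded decomposition raster written by :func:`export_map`."""
    values, grid = read_ascii_grid(raster_path)
    codes = np.where(np.isnan(values), NODATA_CODE, values).astype(np.int16)
    return DecompositionMap(grid, codes, convention)
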