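"""Occurrence records: ingestion, spatial thinning, regional splitting and
predictor extraction against an environmental stack."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence records in map units. ``region`` labels are optional and
    filled by :func:`split_regions`."""

    x: np.ndarray
    y: np.ndarray
    region: np.ndarray | None = None
    species: str = "species"
    source: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.region is not None:
            self.region = np.asarray(self.region, dtype=object)
            if self.region.shape != self.x.shape:
                raise ValueError("region labels must match record count")

    def __len__(self) -> int:
        return self.x.size

    def subset(self, keep: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(
            self.x[keep], self.y[keep],
            None if self.region is None else self.region[keep],
            self.species, self.source,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"species": self.species, "lon": self.x, "lat": self.y})
        if self.region is not None:
            df["region"] = self.region
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str | None = None) -> "OccurrenceSet":
        df = pd.read_csv(path)
        for col in ("lon", "lat"):
            if col not in df.columns:
                raise ValueError(f"{path}: occurrence CSV needs a {col!r} column")
        species = str(df["species"].iloc[0]) if "species" in df.columns and len(df) else "species"
        region = df["region"].to_numpy(dtype=object) if "region" in df.columns else None
        return cls(df["lon"].to_numpy(), df["lat"].to_numpy(), region,
                   species, source or str(path))


@dataclass
class FeatureTable:
    """Per-record layer values with presence/background labels.

    ``data`` columns are exactly the stack's layer names; ``labels`` is 1 for
    presence rows and 0 for background; ``n_dropped`` counts records lost to
    masked cells or out-of-grid coordinates during extraction.
    """

    data: pd.DataFrame
    labels: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.data) != self.labels.size:
            raise ValueError("labels must match table rows")

    @property
    def presence(self) -> pd.DataFrame:
        return self.data[self.labels == 1]

    @property
    def background(self) -> pd.DataFrame:
        return self.data[self.labels == 0]


def thin_occurrences(occ: OccurrenceSet, cell_size: float) -> OccurrenceSet:
    """Keep at most one record per ``cell_size``-sized thinning cell.

    The retained record is the first in input order, which makes thinning
    deterministic and idempotent. Reduces sampling bias and short-range
    spatial autocorrelation in presence data.
    """
    if cell_size <= 0:
        raise ValueError("thinning cell size must be positive")
    seen: set[tuple[int, int]] = set()
    keep = np.zeros(len(occ), dtype=bool)
    cols = np.floor(occ.x / cell_size).astype(int)
    rows = np.floor(occ.y / cell_size).astype(int)
    for i, key in enumerate(zip(rows, cols)):
        if key not in seen:
            seen.add(key)
            keep[i] = True
    return occ.subset(keep)


def split_regions(
    occ: OccurrenceSet,
    boundary: float,
    labels: tuple[str, str] = ("north", "south"),
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Split records at a y-threshold into (north, south).

    Records with ``y >= boundary`` go north — a record exactly on the
    boundary is assigned north (documented tie-break). The two sets are
    disjoint, labeled, and together conserve the input.
    """
    is_north = occ.y >= boundary
    north = occ.subset(is_north)
    south = occ.subset(~is_north)
    north.region = np.full(len(north), labels[0], dtype=object)
    south.region = np.full(len(south), labels[1], dtype=object)
    return north, south


def extract_predictors(occ: OccurrenceSet, stack, label: int = 1) -> FeatureTable:
    """Read layer values at each record's containing cell.

    Records on masked (sea/invalid) cells or outside the grid are dropped;
    the drop count is logged and recorded on the returned table.
    """
    grid = stack.grid
    rows, cols, inside = grid.cell_of(occ.x, occ.y)
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("%d occurrence records fall outside the grid; dropped", n_outside)
    rows, cols = rows[inside], cols[inside]
    unmasked = ~grid.nodata_mask[rows, cols]
    n_masked = int((~unmasked).sum())
    if n_masked:
        logger.warning("%d occurrence records on masked cells; dropped", n_masked)
    rows, cols = rows[unmasked], cols[unmasked]
    data = pd.DataFrame(stack.values_at(rows, cols))
    return FeatureTable(
        data=data,
        labels=np.full(len(data), label, dtype=int),
        n_dropped=n_outside + n_masked,
    )
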