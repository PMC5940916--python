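"""Occurrence hygiene: deduplication, spatial rarefaction to one point per
grid cell, uniform background sampling, and calibration/validation splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid

STAGES = ("raw", "deduplicated", "rarefied")
LABELS = ("presence", "background")


@dataclass
class OccurrenceSet:
    """Planar presence or background points with provenance flags."""

    points: np.ndarray                     # (n, 2) x, y in metres
    stage: str = "raw"
    label: str = "presence"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of x,y coordinates")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path, include_label: bool = False) -> None:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        if include_label:
            df["label"] = self.label
        df.to_csv(path, index=False)


def read_occurrences(path, label: str = "presence") -> OccurrenceSet:
    """Read an ``x,y`` CSV; rows with missing or non-numeric coordinates
    (non-geo-referenced records) are rejected."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "x" not in cols or "y" not in cols:
        raise ValueError(f"occurrence CSV {path} must have x and y columns")
    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    keep = x.notna() & y.notna()
    pts = np.column_stack([x[keep].to_numpy(float), y[keep].to_numpy(float)])
    return OccurrenceSet(pts, stage="raw", label=label)


def clean_and_rarefy(occ: OccurrenceSet, ref: Grid) -> OccurrenceSet:
    """Deduplicate, drop points off the grid or on nodata, then keep the
    first point (input order) per occupied cell of ``ref``.

    The result has at most one point per cell of the active grain, which
    avoids double counting presences during calibration.
    """
    pts = occ.points
    finite = np.isfinite(pts).all(axis=1)
    pts = pts[finite]

    seen: set[tuple[float, float]] = set()
    kept_cells: set[tuple[int, int]] = set()
    out = []
    for x, y in pts:
        key = (x, y)
        if key in seen:
            continue
        seen.add(key)
        row, col = ref.world_to_index(x, y)
        row, col = int(row), int(col)
        if not (0 <= row < ref.n_rows and 0 <= col < ref.n_cols):
            continue
        v = ref.values[row, col]
        if not np.isfinite(v) or v == ref.nodata:
            continue
        if (row, col) in kept_cells:
            continue
        kept_cells.add((row, col))
        out.append((x, y))
    if not out:
        raise ValueError("no occurrence points remain after cleaning and "
                         "rarefaction; cannot model with zero presences")
    return OccurrenceSet(np.array(out), stage="rarefied", label=occ.label)


def sample_background(ref, n: int = 10_000, seed: int = 0) -> OccurrenceSet:
    """Draw ``n`` background points uniformly over valid cells (cells may
    repeat), jittered within the cell.  ``ref`` is a Grid or anything with
    a ``ref_grid``/``valid_mask`` pair (a VariableSet).
    """
    if n <= 0:
        raise ValueError("number of background points must be positive")
    if isinstance(ref, Grid):
        grid, mask = ref, ref.mask()
    else:
        grid, mask = ref.ref_grid(), ref.valid_mask()
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no valid cells to sample background from")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rows.size, size=n)
    u = rng.random(n)
    v = rng.random(n)
    x0, y0 = grid.origin
    x = x0 + (cols[idx] + u) * grid.cell_size
    y = y0 - (rows[idx] + v) * grid.cell_size
    return OccurrenceSet(np.column_stack([x, y]), stage="raw", label="background")


def bootstrap_split(occ: OccurrenceSet, frac: float = 0.75, seed: int = 0,
                    with_replacement: bool = False
                    ) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random calibration/validation split of the occurrence records.

    Default is a partition without replacement with
    ``len(train) == floor(frac * n)``; ``with_replacement=True`` instead
    bootstrap-samples the calibration set and validates on the out-of-bag
    points.
    """
    n = len(occ)
    if n < 4:
        raise ValueError("need at least 4 occurrence records to split")
    if not 0 < frac < 1:
        raise ValueError("train fraction must lie strictly between 0 and 1")
    n_train = int(np.floor(frac * n))
    rng = np.random.default_rng(seed)
    if with_replacement:
        idx = rng.integers(0, n, size=n_train)
        oob = np.setdiff1d(np.arange(n), idx)
        train = OccurrenceSet(occ.points[idx], stage=occ.stage, label=occ.label)
        test = OccurrenceSet(occ.points[oob], stage=occ.stage, label=occ.label)
        return train, test
    perm = rng.permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    train = OccurrenceSet(occ.points[tr], stage=occ.stage, label=occ.label)
    test = OccurrenceSet(occ.points[te], stage=occ.stage, label=occ.label)
    return train, test
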