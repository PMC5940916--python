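"""Assemble the three predictor variable sets and screen collinearity.

VS-1 mimics the "customary" setup: coarse bioclimatic surfaces (BCV) plus
the biophysical layers (BPV) resampled to the 1 km climate grain.  VS-2 and
VS-3 drop the climate layers to conserve the finer grain of the biophysical
predictors (300 m and 50 m respectively).  Continuous layers are resampled
bilinearly, categorical land cover by nearest neighbour.

A Pearson screen at the evaluation points removes one member of every layer
pair with |r| above the cutoff (default 0.70).  Absolute correlation is
used: strong negative collinearity is as harmful as positive.  Categorical
land cover is excluded from the screen (Pearson is undefined on class
codes) and always retained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CATEGORICAL, CONTINUOUS, Grid, resample
from .landscape import BCV, BPV, LandscapeBundle
from .occurrences import OccurrenceSet

VS_GRAINS = {"VS-1": 1000.0, "VS-2": 300.0, "VS-3": 50.0}
GRAIN_NAMES = {v: k for k, v in VS_GRAINS.items()}


@dataclass
class VariableSet:
    """Named, aligned predictor layers at one grain size."""

    name: str
    grain: float
    layers: dict[str, Grid]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("variable set must contain at least one layer")
        ref = next(iter(self.layers.values()))
        for n, g in self.layers.items():
            if not g.same_geometry(ref):
                raise ValueError(f"layer {n!r} not aligned in {self.name}")
            if abs(g.cell_size - self.grain) > 1e-9:
                raise ValueError(
                    f"layer {n!r} grain {g.cell_size} != stated grain {self.grain}")

    def names(self) -> list[str]:
        return list(self.layers)

    def continuous_names(self) -> list[str]:
        return [n for n, g in self.layers.items() if g.kind == CONTINUOUS]

    def categorical_names(self) -> list[str]:
        return [n for n, g in self.layers.items() if g.kind == CATEGORICAL]

    def ref_grid(self) -> Grid:
        return next(iter(self.layers.values()))

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.ref_grid().shape, dtype=bool)
        for g in self.layers.values():
            mask &= g.mask()
        return mask

    def extract(self, points: np.ndarray) -> pd.DataFrame:
        """Layer values at planar points; off-grid / nodata become NaN."""
        pts = np.asarray(points, dtype=float)
        out = {}
        for n, g in self.layers.items():
            v = g.value_at(pts[:, 0], pts[:, 1])
            out[n] = np.where(v == g.nodata, np.nan, v)
        return pd.DataFrame(out)

    def subset(self, names) -> "VariableSet":
        return VariableSet(self.name, self.grain,
                           {n: self.layers[n] for n in names},
                           {n: self.categories[n] for n in names})


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix over continuous layers and the drop log."""

    r: pd.DataFrame
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)   # zero-variance layers

    def to_csv(self, path) -> None:
        self.r.to_csv(path)


def make_northness(aspect: Grid) -> Grid:
    """cos(aspect): +1 facing north, -1 facing south; flat cells neutral 0."""
    vals = np.where(aspect.mask(), np.cos(np.radians(aspect.values)), 0.0)
    return Grid(vals, origin=aspect.origin, cell_size=aspect.cell_size,
                nodata=aspect.nodata, kind=CONTINUOUS)


def build_variable_sets(fine: LandscapeBundle,
                        climate: LandscapeBundle | None = None,
                        aspect_mode: str = "degrees",
                        ) -> dict[str, VariableSet]:
    """Build VS-1 (1 km, BCV + resampled BPV), VS-2 (300 m BPV) and VS-3
    (50 m BPV) from a native-grain bundle.

    ``aspect_mode='northness'`` replaces the aspect layer with cos(aspect)
    before any resampling, avoiding the 0/360 degree wrap under bilinear
    interpolation.
    """
    if aspect_mode not in ("degrees", "northness"):
        raise ValueError(f"unknown aspect_mode {aspect_mode!r}")
    bpv = fine.bpv()
    for required in ("altitude", "slope", "aspect", "landcover", "dist_water"):
        if required not in bpv:
            raise ValueError(f"fine bundle is missing BPV layer {required!r}")
    if climate is None:
        climate = fine.bcv()

    bpv_layers = dict(bpv.grids)
    if aspect_mode == "northness":
        bpv_layers["northness"] = make_northness(bpv_layers.pop("aspect"))

    out: dict[str, VariableSet] = {}
    for name, grain in VS_GRAINS.items():
        layers: dict[str, Grid] = {}
        cats: dict[str, str] = {}
        if name == "VS-1":
            for n, g in climate.grids.items():
                layers[n] = resample(g, grain)
                cats[n] = BCV
        for n, g in bpv_layers.items():
            layers[n] = g if abs(g.cell_size - grain) < 1e-9 else resample(g, grain)
            cats[n] = BPV
        out[name] = VariableSet(name, grain, layers, cats)
    return out


def scenario_for_grain(vsets: dict[str, VariableSet], grain: float) -> VariableSet:
    name = GRAIN_NAMES.get(float(grain))
    if name is None or name not in vsets:
        raise ValueError(f"no variable set at grain {grain} m")
    return vsets[name]


def pearson_matrix(vs: VariableSet, pts) -> CorrelationReport:
    """Pearson r over continuous layer values extracted at the points.

    Zero-variance layers yield undefined correlations; they are recorded
    with r = 1 against themselves, 0 elsewhere, and flagged.
    """
    if isinstance(pts, OccurrenceSet):
        pts = pts.points
    names = vs.continuous_names()
    df = vs.extract(pts)[names].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 on-grid points for a Pearson screen")
    x = df.to_numpy(float)
    sd = x.std(axis=0)
    flagged = [n for n, s in zip(names, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    r[~np.isfinite(r)] = 0.0
    r = 0.5 * (r + r.T)          # corrcoef is only symmetric up to rounding
    np.fill_diagonal(r, 1.0)
    return CorrelationReport(pd.DataFrame(r, index=names, columns=names),
                             flagged=flagged)


def collinearity_filter(report: CorrelationReport, cutoff: float = 0.70
                        ) -> list[str]:
    """Greedy elimination until no pair exceeds |r| > cutoff.

    At each step the worst-offending pair is found; the member with the
    larger mean absolute correlation to all remaining layers is dropped
    (alphabetical tie-break).  Operating on alphabetically ordered names
    makes the result independent of input layer listing.  Dropped layers
    are appended to ``report.dropped`` as (layer, culprit partner, r).
    """
    retained = sorted(report.r.index)
    while len(retained) > 1:
        sub = report.r.loc[retained, retained].to_numpy()
        absr = np.abs(sub)
        np.fill_diagonal(absr, 0.0)
        worst = absr.max()
        if worst <= cutoff:
            break
        pairs = [(retained[i], retained[j])
                 for i in range(len(retained)) for j in range(i + 1, len(retained))
                 if absr[i, j] == worst]
        a, b = min(pairs)                       # lexicographically smallest pair
        mean_a = _mean_abs_corr(report, a, retained)
        mean_b = _mean_abs_corr(report, b, retained)
        if mean_a > mean_b:
            drop, partner = a, b
        elif mean_b > mean_a:
            drop, partner = b, a
        else:
            drop, partner = max(a, b), min(a, b)   # tie: drop the later name
        report.dropped.append((drop, partner, float(report.r.loc[drop, partner])))
        retained.remove(drop)
    return retained


def _mean_abs_corr(report: CorrelationReport, name: str, pool: list[str]) -> float:
    others = [n for n in pool if n != name]
    if not others:
        return 0.0
    return float(np.abs(report.r.loc[name, others].to_numpy()).mean())


def filter_variable_set(vs: VariableSet, pts, cutoff: float = 0.70
                        ) -> tuple[VariableSet, CorrelationReport]:
    """Pearson-screen the continuous layers of ``vs`` at the points and
    return the filtered set (categorical layers always retained) plus the
    correlation report."""
    report = pearson_matrix(vs, pts)
    retained = collinearity_filter(report, cutoff=cutoff)
    keep = [n for n in vs.names()
            if n in retained or vs.layers[n].kind == CATEGORICAL]
    return vs.subset(keep), report
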