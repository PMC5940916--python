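"""Synthetic landscapes and a virtual habitat-specialist species.

The generator emulates the predictor inventory of an upland-UK style study
area: a fine-grain (50 m) digital elevation model with slope and aspect
derived from it, a categorical land-cover map correlated with altitude, a
distance-from-water-channels surface, and two very smooth "climate"
surfaces that only carry information at coarse (>= 1 km) grain.  A second
landscape generated with a different seed and shifted relief / land-cover
mixture stands in for a topographically distinct transfer area.

The virtual species is a habitat specialist: it prefers one land-cover
class (the woodland analogue), an altitude optimum, shallow slopes, a
northerly aspect, and proximity to water channels.  Its true suitability
surface is

    S = logistic( amp * exp(-((alt - opt)/tol)^2 / 2)
                  + slope_coef * zscore(slope)
                  + northness_coef * cos(aspect)
                  - water_decay * dist_water
                  + bonus * 1[landcover == preferred] )

so every coefficient has a recoverable sign and the surface lives in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, stats

from .grid import (CATEGORICAL, CONTINUOUS, Grid, distance_to_channels,
                   read_ascii, slope_aspect, write_ascii)
from .occurrences import OccurrenceSet

BPV = "BPV"   # biophysical: topography, land cover, water distance
BCV = "BCV"   # bioclimatic: smooth coarse climate surfaces

BPV_LAYERS = ("altitude", "slope", "aspect", "landcover", "dist_water")
BCV_LAYERS = ("clim_temp", "clim_prec")


@dataclass
class LandscapeParams:
    """Knobs of the synthetic landscape generator.

    extent_cells : (rows, cols) at the native 50 m grain; at least (60, 60)
        so a 1 km resample retains a 3x3 grid.
    terrain_relief : target altitude range in metres.
    terrain_corr_length : Gaussian-random-field correlation length (m).
    n_landcover_classes : number of land-cover classes (2..10).
    channel_density : fraction of cells seeded as channel sources.
    climate_corr_length : correlation length (m) of the climate surfaces;
        >= 1000 so they are smooth at coarse grain.
    landcover_altitude_weight : weight of altitude (vs. an independent
        random field) in the land-cover mixture; shifting it between
        landscapes changes the character of the class mosaic.
    """

    extent_cells: tuple[int, int] = (200, 200)
    terrain_relief: float = 900.0
    terrain_corr_length: float = 1500.0
    n_landcover_classes: int = 5
    channel_density: float = 0.002
    climate_corr_length: float = 5000.0
    landcover_altitude_weight: float = 0.5
    cell_size: float = 50.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.extent_cells) < 60:
            raise ValueError("extent_cells must be at least (60, 60)")
        if not self.terrain_corr_length > 0:
            raise ValueError("terrain_corr_length must be > 0")
        if not 2 <= self.n_landcover_classes <= 10:
            raise ValueError("n_landcover_classes must be in 2..10")
        if not self.terrain_relief > 0:
            raise ValueError(
                "degenerate terrain: terrain_relief must be > 0 "
                "(zero-variance altitude cannot yield slope or aspect)")
        if not self.climate_corr_length >= 1000:
            raise ValueError("climate_corr_length must be >= 1000 m")
        if not 0 < self.channel_density <= 0.2:
            raise ValueError("channel_density must be in (0, 0.2]")


@dataclass
class SpeciesParams:
    """Virtual habitat-specialist response parameters.

    Signs follow the specialist's ecology: negative ``slope_coef`` prefers
    shallow slopes, positive ``northness_coef`` a northerly aspect,
    positive ``water_decay`` (1/m) decays suitability away from channels,
    and ``preferred_landcover`` is the woodland-analogue class.
    """

    preferred_landcover: int = 1
    altitude_opt: float = 150.0
    altitude_tol: float = 120.0
    slope_coef: float = -0.5
    northness_coef: float = 0.5
    water_decay: float = 0.002
    altitude_amp: float = 2.0
    landcover_bonus: float = 1.5
    n_presences: int = 152
    seed: int = 0

    def validate(self) -> None:
        if not self.altitude_tol > 0:
            raise ValueError("altitude_tol must be > 0")
        if self.water_decay < 0:
            raise ValueError("water_decay must be >= 0")
        if self.n_presences < 30:
            raise ValueError("n_presences must be >= 30")


@dataclass
class LandscapeBundle:
    """Named, mutually aligned Grids at one grain size."""

    grids: dict[str, Grid]
    categories: dict[str, str]

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("bundle must contain at least one layer")
        ref = next(iter(self.grids.values()))
        for name, g in self.grids.items():
            if not g.same_geometry(ref):
                raise ValueError(f"layer {name!r} is not aligned with the bundle")

    @property
    def cell_size(self) -> float:
        return next(iter(self.grids.values())).cell_size

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self.grids

    def names(self) -> list[str]:
        return list(self.grids)

    def subset(self, names) -> "LandscapeBundle":
        return LandscapeBundle({n: self.grids[n] for n in names},
                               {n: self.categories[n] for n in names})

    def bpv(self) -> "LandscapeBundle":
        return self.subset([n for n, c in self.categories.items() if c == BPV])

    def bcv(self) -> "LandscapeBundle":
        return self.subset([n for n, c in self.categories.items() if c == BCV])


@dataclass
class VirtualTruth:
    """Ground-truth suitability surface for a virtual species."""

    suitability: Grid
    params: SpeciesParams

    def __post_init__(self) -> None:
        v = self.suitability.values[self.suitability.mask()]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("true suitability must lie in [0, 1]")


# -- random-field machinery -------------------------------------------------

def gaussian_random_field(shape: tuple[int, int], corr_cells: float,
                          rng: np.random.Generator) -> np.ndarray:
    """White noise filtered with a Gaussian kernel of the stated correlation
    length (in cells), normalised to zero mean and unit variance."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_cells, mode="reflect")
    sd = f.std()
    if sd == 0:
        raise ValueError("degenerate random field (zero variance)")
    return (f - f.mean()) / sd


def _uniform_rank(a: np.ndarray) -> np.ndarray:
    """Rank-transform to (0, 1]; makes quantile thresholds exact."""
    r = stats.rankdata(a.ravel(), method="average")
    return (r / a.size).reshape(a.shape)


def _trace_channels(alt: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Steepest-descent trace from each source cell to the grid edge or a
    pit (no hydrological pit-filling).  Returns a 0/1 channel mask."""
    nr, nc = alt.shape
    mask = np.zeros((nr, nc), dtype=bool)
    nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r, c in sources:
        r, c = int(r), int(c)
        while True:
            mask[r, c] = True
            if r == 0 or c == 0 or r == nr - 1 or c == nc - 1:
                break                       # reached the grid edge
            best, best_z = None, alt[r, c]
            for dr, dc in nbrs:
                z = alt[r + dr, c + dc]
                if z < best_z:
                    best, best_z = (r + dr, c + dc), z
            if best is None:
                break                       # pit terminates the trace
            r, c = best
    return mask


# -- generators -------------------------------------------------------------

def generate_landscape(params: LandscapeParams) -> LandscapeBundle:
    """Generate an aligned native-grain landscape bundle.

    Layers: altitude (Gaussian random field rescaled to ``terrain_relief``),
    slope and aspect (Horn derivatives of altitude), land cover (quantile
    thresholds of an altitude + independent-field mixture), distance from
    water channels (exact distance to a steepest-descent channel trace),
    and two smooth climate surfaces.  Deterministic given ``seed``.
    """
    params.validate()
    nr, nc = params.extent_cells
    cs = params.cell_size
    ss = np.random.SeedSequence(params.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in ss]

    geo = dict(origin=(0.0, 0.0), cell_size=cs)

    # terrain
    corr_cells = params.terrain_corr_length / cs
    f = gaussian_random_field((nr, nc), corr_cells, rngs[0])
    rng_span = f.max() - f.min()
    alt_vals = (f - f.min()) / rng_span * params.terrain_relief
    altitude = Grid(alt_vals, kind=CONTINUOUS, **geo)
    slope, aspect = slope_aspect(altitude)

    # land cover: mixture of altitude quantiles and an independent field
    g2 = gaussian_random_field((nr, nc), corr_cells, rngs[1])
    w = params.landcover_altitude_weight
    score = w * _uniform_rank(alt_vals) + (1 - w) * _uniform_rank(g2)
    score = _uniform_rank(score)
    k = params.n_landcover_classes
    lc_vals = np.minimum((score * k).astype(int), k - 1).astype(float)
    landcover = Grid(lc_vals, kind=CATEGORICAL, **geo)

    # water channels traced downhill from random source cells
    n_src = max(1, int(round(params.channel_density * nr * nc)))
    flat_idx = rngs[2].choice(nr * nc, size=n_src, replace=False)
    sources = np.column_stack(np.unravel_index(flat_idx, (nr, nc)))
    chan_mask = _trace_channels(alt_vals, sources)
    channels = Grid(chan_mask.astype(float), kind=CATEGORICAL, **geo)
    dist_water = distance_to_channels(channels)

    # smooth climate surfaces (informative only at coarse grain)
    clim_cells = params.climate_corr_length / cs
    t = gaussian_random_field((nr, nc), clim_cells, rngs[3])
    p = gaussian_random_field((nr, nc), clim_cells, rngs[4])
    clim_temp = Grid(9.0 + 3.0 * t, kind=CONTINUOUS, **geo)
    clim_prec = Grid(1200.0 + 400.0 * p, kind=CONTINUOUS, **geo)

    grids = {"altitude": altitude, "slope": slope, "aspect": aspect,
             "landcover": landcover, "dist_water": dist_water,
             "clim_temp": clim_temp, "clim_prec": clim_prec}
    categories = {n: (BPV if n in BPV_LAYERS else BCV) for n in grids}
    return LandscapeBundle(grids, categories)


def transfer_params(train: LandscapeParams, seed_offset: int = 1000
                    ) -> LandscapeParams:
    """Parameters for a topographically distinct transfer landscape: new
    seed, shifted relief and a different land-cover mixture."""
    d = asdict(train)
    d["seed"] = train.seed + seed_offset
    d["terrain_relief"] = 0.65 * train.terrain_relief
    d["landcover_altitude_weight"] = max(
        0.0, min(1.0, train.landcover_altitude_weight - 0.15))
    d["extent_cells"] = tuple(d["extent_cells"])
    return LandscapeParams(**d)


def true_suitability(bundle: LandscapeBundle, sp: SpeciesParams) -> VirtualTruth:
    """Evaluate the documented suitability formula on a native-grain bundle."""
    sp.validate()
    for name in BPV_LAYERS:
        if name not in bundle:
            raise ValueError(f"bundle is missing required layer {name!r}")
    alt = bundle["altitude"]
    slope = bundle["slope"]
    aspect = bundle["aspect"]
    lc = bundle["landcover"]
    dw = bundle["dist_water"]

    valid = alt.mask() & slope.mask() & lc.mask() & dw.mask()
    a = alt.values
    s = slope.values
    sv = s[valid]
    s_sd = sv.std()
    s_std = (s - sv.mean()) / s_sd if s_sd > 0 else np.zeros_like(s)

    # flat cells have undefined aspect; treat their northness as neutral (0)
    northness = np.where(aspect.mask(), np.cos(np.radians(aspect.values)), 0.0)

    z = (sp.altitude_amp * np.exp(-0.5 * ((a - sp.altitude_opt) / sp.altitude_tol) ** 2)
         + sp.slope_coef * s_std
         + sp.northness_coef * northness
         - sp.water_decay * dw.values
         + sp.landcover_bonus * (lc.values == sp.preferred_landcover))
    suit = 1.0 / (1.0 + np.exp(-z))
    nod = alt.nodata
    vals = np.where(valid, suit, nod)
    grid = Grid(vals, origin=alt.origin, cell_size=alt.cell_size,
                nodata=nod, kind=CONTINUOUS)
    return VirtualTruth(grid, sp)


def sample_presences(truth: VirtualTruth, n: int, seed: int) -> OccurrenceSet:
    """Draw ``n`` presence points from cells with probability proportional
    to true suitability, jittered uniformly within the chosen cell."""
    if n < 1:
        raise ValueError("need at least one presence point")
    g = truth.suitability
    mask = g.mask()
    w = np.where(mask, g.values, 0.0).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("true suitability is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    idx = rng.choice(w.size, size=n, replace=True, p=w / total)
    rows, cols = np.unravel_index(idx, g.shape)
    u = rng.random(n)
    v = rng.random(n)
    x0, y0 = g.origin
    x = x0 + (cols + u) * g.cell_size
    y = y0 - (rows + v) * g.cell_size
    return OccurrenceSet(np.column_stack([x, y]), stage="raw", label="presence")


# -- bundle I/O -------------------------------------------------------------

def write_bundle(bundle: LandscapeBundle, outdir) -> None:
    """One Esri ASCII grid per layer plus a plain-text manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.txt", "w") as fh:
        for name, g in bundle.grids.items():
            write_ascii(g, outdir / f"{name}.asc")
            fh.write(f"{name}:{g.kind}:{bundle.categories[name]}\n")


def read_bundle(indir) -> LandscapeBundle:
    indir = Path(indir)
    grids: dict[str, Grid] = {}
    categories: dict[str, str] = {}
    with open(indir / "manifest.txt") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, kind, cat = line.split(":")
            grids[name] = read_ascii(indir / f"{name}.asc", kind=kind)
            categories[name] = cat
    return LandscapeBundle(grids, categories)
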