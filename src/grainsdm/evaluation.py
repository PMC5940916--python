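"""Model assessment: presence-background AUC, the binned and continuous
Boyce index, permutation importance and response curves.

AUC uses the background points as pseudo-absences (the classic convention
for presence-only models): it is the Mann-Whitney probability that a
presence outscores a background point, ties counted one half.

The Boyce index reclassifies the suitability map into classes (equal-width
bins, rank-quantile bins, or overlapping moving windows).  Per class, the
Predicted frequency P is the share of presence points whose cell falls in
the class and the Expected frequency E is the share of grid cells in the
class; the index is the Spearman rank correlation of the P/E ratio with
class order.  +1 means predictions consistent with the presences, 0 a
random model, -1 counter predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid
from .occurrences import OccurrenceSet


def auc(pres_scores, bg_scores) -> float:
    """Mann-Whitney AUC of presence vs background scores (ties count 1/2)."""
    p = np.asarray(pres_scores, dtype=float)
    b = np.asarray(bg_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be non-empty")
    if not (np.isfinite(p).all() and np.isfinite(b).all()):
        raise ValueError("non-finite scores")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def spearman_rho(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Spearman rank correlation with a one-tailed p-value (large-sample t
    approximation).  Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BoyceCurve:
    """Suitability classes with predicted/expected frequencies and the
    P/E-vs-class rank correlation (the Boyce index)."""

    centers: np.ndarray          # class centres along the suitability axis
    P: np.ndarray                # predicted frequency per class
    E: np.ndarray                # expected frequency per class
    F: np.ndarray                # P/E ratio (nan where E == 0)
    rho: float
    p_value: float
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"center": self.centers, "P": self.P,
                             "E": self.E, "F": self.F})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _presence_suitabilities(suit: Grid, presences) -> np.ndarray:
    if isinstance(presences, OccurrenceSet):
        presences = presences.points
    pts = np.asarray(presences, dtype=float)
    v = suit.value_at(pts[:, 0], pts[:, 1])
    v = v[(v != suit.nodata) & np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no presence falls on a valid cell of the map")
    return v


def boyce(suit_map, presences, mode: str = "continuous", nbins: int = 10,
          binning: str = "width", window_width: float | None = None,
          n_steps: int = 100) -> BoyceCurve:
    """Boyce index of a suitability map against presence points.

    mode="binned" partitions the suitability range into ``nbins`` classes
    (equal width, or equal cell counts with ``binning='quantile'``);
    mode="continuous" slides an overlapping window (default width 1/10 of
    the range) in ``n_steps`` increments.  Classes with E = 0 carry an
    undefined P/E and are excluded from the rank correlation.
    """
    suit = suit_map.logistic if hasattr(suit_map, "logistic") else suit_map
    cells = suit.values[suit.mask()]
    if cells.size == 0:
        raise ValueError("suitability map has no valid cells")
    pres = _presence_suitabilities(suit, presences)
    vmin, vmax = float(cells.min()), float(cells.max())
    if vmax <= vmin:
        raise ValueError("constant suitability map; Boyce index undefined")

    if mode == "binned":
        if binning == "width":
            edges = np.linspace(vmin, vmax, nbins + 1)
        elif binning == "quantile":
            qs = np.linspace(0, 1, nbins + 1)
            edges = np.unique(np.quantile(cells, qs))
            if edges.size < 3:
                raise ValueError("too few distinct values for quantile bins")
        else:
            raise ValueError(f"unknown binning {binning!r}")
        cell_counts, _ = np.histogram(cells, bins=edges)
        pres_counts, _ = np.histogram(pres, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        P = pres_counts / pres.size
        E = cell_counts / cells.size
    elif mode == "continuous":
        width = window_width if window_width is not None else (vmax - vmin) / 10.0
        if not width > 0:
            raise ValueError("window_width must be positive")
        step = (vmax - vmin) / n_steps
        centers = np.arange(vmin + width / 2, vmax - width / 2 + step / 2, step)
        if centers.size < 3:
            centers = np.linspace(vmin + width / 2, vmax - width / 2, 3)
        cs = np.sort(cells)
        ps = np.sort(pres)
        lo = centers - width / 2
        hi = centers + width / 2
        E = (np.searchsorted(cs, hi, side="right")
             - np.searchsorted(cs, lo, side="left")) / cells.size
        P = (np.searchsorted(ps, hi, side="right")
             - np.searchsorted(ps, lo, side="left")) / pres.size
    else:
        raise ValueError(f"unknown Boyce mode {mode!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(E > 0, P / E, np.nan)
    defined = E > 0
    if defined.sum() < 3:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = spearman_rho(np.arange(len(F))[defined], F[defined])
    return BoyceCurve(centers=centers, P=P, E=E, F=F, rho=rho, p_value=p,
                      mode=mode)


def cbi(suit_map, presences, **kwargs) -> float:
    """Continuous Boyce Index: the headline transferability metric."""
    return boyce(suit_map, presences, mode="continuous", **kwargs).rho


def permutation_importance(model, X_pres: pd.DataFrame, X_bg: pd.DataFrame,
                           seed: int = 0, n_repeats: int = 1) -> pd.Series:
    """Percent importance per variable from the training-AUC drop after
    permuting that variable across the combined evaluation points;
    normalised to sum to 100."""
    rng = np.random.default_rng(seed)
    base = auc(model.predict_logistic(X_pres), model.predict_logistic(X_bg))
    n_p = len(X_pres)
    combined = pd.concat([X_pres, X_bg], ignore_index=True)
    drops = {}
    for var in model.variables_:
        acc = 0.0
        for _ in range(n_repeats):
            perm = combined.copy()
            perm[var] = rng.permutation(perm[var].to_numpy())
            sp = model.predict_logistic(perm.iloc[:n_p])
            sb = model.predict_logistic(perm.iloc[n_p:])
            acc += max(0.0, base - auc(sp, sb))
        drops[var] = acc / n_repeats
    s = pd.Series(drops)
    total = s.sum()
    if total == 0:
        return pd.Series(100.0 / len(s), index=s.index)
    return 100.0 * s / total


def response_curve(model, variable: str, n_points: int = 100) -> pd.DataFrame:
    """Sweep one variable across its training range with all other
    variables held at background means (categorical at the modal class);
    returns (value, suitability) pairs."""
    if variable not in model.variables_:
        raise ValueError(f"variable {variable!r} not in model")
    base: dict[str, np.ndarray] = {}
    for v in model.variables_:
        if v in model.classes_:
            base[v] = np.full(n_points, float(model.modal_class_[v]))
        else:
            base[v] = np.full(n_points, float(model.background_means_[v]))
    if variable in model.classes_:
        sweep = np.array(sorted(model.classes_[variable]), dtype=float)
        for v in base:
            base[v] = base[v][:sweep.size]
        base[variable] = sweep
    else:
        lo = float(model.clamp_min_[variable])
        hi = float(model.clamp_max_[variable])
        sweep = np.linspace(lo, hi, n_points)
        base[variable] = sweep
    X = pd.DataFrame(base)
    return pd.DataFrame({"value": sweep,
                         "suitability": model.predict_logistic(X)})


@dataclass
class EvaluationResult:
    """Aggregate assessment of one modelling scenario."""

    auc_train: float
    auc_test: float
    cbi: float
    permutation_importance: pd.Series
    boyce_curve: BoyceCurve
    response_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
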