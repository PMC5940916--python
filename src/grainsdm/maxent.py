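"""Presence-background maximum-entropy species distribution model.

The model estimates the Gibbs distribution of maximum entropy over the
background, p(x) proportional to exp(sum_j lambda_j f_j(x)), subject to the
presence feature expectations, by maximising the L1-penalised log-likelihood
of the presence sample:

    G(lambda) = mean_pres[ lambda . f ]  -  log mean_bg[ exp(lambda . f) ]
                -  sum_j beta_j |lambda_j|

G is the regularised *gain* (zero for the uniform model); it is concave, so
any quasi-Newton ascent is monotone and the recorded gain trajectory must be
non-decreasing.  Features are linear + quadratic terms for continuous
variables and one indicator per class for categorical ones; continuous
features are standardised by background mean/std.  The L1 weight per feature
is ``reg_beta * std_bg(f_j) / sqrt(n_presences)``.

Outputs follow the classic MaxEnt conventions: the *raw* output is the
normalised Gibbs density (sums to 1 over the evaluated cells) and the
*logistic* output is ``e^H * raw / (1 + e^H * raw)`` with H the entropy of
the fitted raw distribution over the training background.  When projecting,
features can be clamped to their training range, and "fade by clamping"
additionally subtracts the absolute logistic difference between the clamped
and unclamped predictions (floored at zero) so that heavily clamped cells
fade from the map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .grid import CONTINUOUS, Grid
from .occurrences import OccurrenceSet, bootstrap_split, sample_background
from .seeds import subseed
from .variables import VariableSet

CLAMP_MODES = ("none", "clamp", "fade")


def extract_point_values(vs: VariableSet, points) -> pd.DataFrame:
    """Layer values at points; raises if any point sits on nodata or off
    the grid, listing the offending point indices."""
    if isinstance(points, OccurrenceSet):
        points = points.points
    df = vs.extract(points)
    bad = df.isna().any(axis=1)
    if bad.any():
        idx = list(np.nonzero(bad.to_numpy())[0][:10])
        raise ValueError(
            f"{int(bad.sum())} point(s) fall on nodata or outside the grid "
            f"(first offenders at indices {idx})")
    return df


class MaxEnt:
    """Scikit-learn style presence-background maximum-entropy estimator.

    Parameters
    ----------
    categorical : sequence of str
        Column names to expand into per-class indicators.
    quadratic : bool
        Add squared terms for continuous variables.
    standardize : bool
        Standardise expanded continuous features by background mean/std.
    reg_beta : float
        Base L1 regularisation weight (scaled per feature; see module doc).
    max_iter : int
        Iteration budget of the optimiser.
    tol : float
        Convergence threshold on the per-iteration change of regularised
        gain.

    Attributes (after ``fit``)
    --------------------------
    lambdas_ : pd.Series           fitted coefficients per feature
    feature_names_ : list[str]
    clamp_min_, clamp_max_ : pd.Series   per-feature training ranges
    log_z_ : float                 log partition value over background
    entropy_ : float               entropy H of the fitted raw distribution
    gain_trajectory_ : np.ndarray  regularised gain per iteration
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, categorical=(), quadratic=True, standardize=True,
                 reg_beta=1.0, max_iter=5000, tol=1e-6):
        self.categorical = tuple(categorical)
        self.quadratic = quadratic
        self.standardize = standardize
        self.reg_beta = reg_beta
        self.max_iter = max_iter
        self.tol = tol

    # sklearn plumbing ------------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {"categorical": self.categorical, "quadratic": self.quadratic,
                "standardize": self.standardize, "reg_beta": self.reg_beta,
                "max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "MaxEnt":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # feature expansion -----------------------------------------------------

    def _learn_expansion(self, X: pd.DataFrame) -> None:
        self.variables_ = list(X.columns)
        self.classes_ = {}
        for c in self.categorical:
            if c not in X.columns:
                raise ValueError(f"categorical variable {c!r} not in data")
            self.classes_[c] = sorted(int(v) for v in np.unique(X[c].to_numpy()))

    def _expand(self, X: pd.DataFrame) -> pd.DataFrame:
        """Unstandardised feature expansion (linear + quadratic + indicators)."""
        cols: dict[str, np.ndarray] = {}
        for name in self.variables_:
            v = X[name].to_numpy(dtype=float)
            if name in self.classes_:
                for cls in self.classes_[name]:
                    cols[f"{name}=={cls}"] = (v == cls).astype(float)
            else:
                cols[name] = v
                if self.quadratic:
                    cols[f"{name}^2"] = v * v
        return pd.DataFrame(cols)

    def _design(self, X: pd.DataFrame, clamp: bool):
        """Standardised design matrix; returns (Z, clamped_any_row)."""
        F = self._expand(X)[self.feature_names_]
        A = F.to_numpy(float)
        lo = self.clamp_min_.to_numpy()
        hi = self.clamp_max_.to_numpy()
        flags = (A < lo) | (A > hi)
        if clamp:
            A = np.clip(A, lo, hi)
        Z = (A - self.mean_.to_numpy()) / self.std_.to_numpy()
        return Z, flags.any(axis=1)

    # fitting ---------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y) -> "MaxEnt":
        """Fit on stacked presence/background rows.

        ``y`` is 1 for presence rows and 0 for background rows.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.isfinite(X.to_numpy(float)).all():
            raise ValueError("non-finite values in feature data")
        n_pres = int((y == 1).sum())
        n_bg = int((y == 0).sum())
        if n_pres < 2:
            raise ValueError("need at least 2 presence rows")
        if n_bg < n_pres:
            raise ValueError("background rows must be at least as numerous "
                             "as presence rows")

        self._learn_expansion(X)
        F = self._expand(X)
        self.feature_names_ = list(F.columns)
        A = F.to_numpy(float)
        pres = y == 1
        bg = y == 0

        self.clamp_min_ = pd.Series(A.min(axis=0), index=self.feature_names_)
        self.clamp_max_ = pd.Series(A.max(axis=0), index=self.feature_names_)
        if self.standardize:
            mu = A[bg].mean(axis=0)
            sd = A[bg].std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(A.shape[1])
            sd = np.ones(A.shape[1])
        self.mean_ = pd.Series(mu, index=self.feature_names_)
        self.std_ = pd.Series(sd, index=self.feature_names_)

        Z = (A - mu) / sd
        Zp, Zb = Z[pres], Z[bg]
        fbar = Zp.mean(axis=0)
        beta = self.reg_beta * Zb.std(axis=0) / np.sqrt(n_pres)
        self.beta_ = pd.Series(beta, index=self.feature_names_)

        # raw-variable summaries used by response curves / importance
        self.background_means_ = X.iloc[np.nonzero(bg)[0]].mean(numeric_only=True)
        self.modal_class_ = {
            c: int(pd.Series(X[c][bg]).mode().iloc[0]) for c in self.classes_}
        self.n_presences_ = n_pres
        self.n_background_ = n_bg

        k = Z.shape[1]

        def gain_of(lam: np.ndarray) -> float:
            s_bg = Zb @ lam
            return float(fbar @ lam - logsumexp(s_bg) + np.log(n_bg)
                         - beta @ np.abs(lam))

        def objective(theta: np.ndarray):
            p, m = theta[:k], theta[k:]
            lam = p - m
            s_bg = Zb @ lam
            a = logsumexp(s_bg)
            g = fbar @ lam - a + np.log(n_bg) - beta @ (p + m)
            q = np.exp(s_bg - a)
            grad_lam = fbar - q @ Zb
            grad = np.concatenate([-grad_lam + beta, grad_lam + beta])
            return -g, grad

        gains = [0.0]
        stopped_by_tol = False

        def callback(theta):
            nonlocal stopped_by_tol
            p, m = theta[:k], theta[k:]
            g = gain_of(p - m)
            improved = g - gains[-1]
            gains.append(g)
            if improved < self.tol:
                stopped_by_tol = True
                raise StopIteration

        theta0 = np.zeros(2 * k)
        bounds = [(0.0, None)] * (2 * k)
        res = optimize.minimize(
            objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            callback=callback,
            options={"maxiter": self.max_iter, "ftol": 1e-18, "gtol": 1e-10,
                     "maxfun": 10 * self.max_iter + 100})

        theta = res.x
        lam = theta[:k] - theta[k:]
        self.lambdas_ = pd.Series(lam, index=self.feature_names_)
        s_bg = Zb @ lam
        self.log_z_ = float(logsumexp(s_bg))
        q = np.exp(s_bg - self.log_z_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-(q * np.where(q > 0, np.log(q), 0.0)).sum())
        self.gain_trajectory_ = np.array(gains)
        self.gain_ = gain_of(lam)
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(stopped_by_tol or res.success or res.nit < self.max_iter)
        if not self.converged_:
            warnings.warn("MaxEnt fit did not converge within the iteration "
                          "budget", RuntimeWarning)
        return self

    # prediction ------------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "lambdas_"):
            raise RuntimeError("model is not fitted")

    def linear_scores(self, X: pd.DataFrame, clamp: bool = False):
        """Linear predictor lambda . f at each row; also returns the
        per-row clamp flag."""
        self._check_fitted()
        X = pd.DataFrame(X)
        missing = [v for v in self.variables_ if v not in X.columns]
        if missing:
            raise ValueError(f"missing variables in prediction data: {missing}")
        Z, flags = self._design(X[self.variables_], clamp)
        return Z @ self.lambdas_.to_numpy(), flags

    def predict_logistic(self, X: pd.DataFrame, clamp_mode: str = "none"
                         ) -> np.ndarray:
        """Pointwise logistic suitability: sigmoid(H + s - log Z)."""
        if clamp_mode not in CLAMP_MODES:
            raise ValueError(f"unknown clamp_mode {clamp_mode!r}")
        s_u, _ = self.linear_scores(X, clamp=False)
        lu = _sigmoid(self.entropy_ + s_u - self.log_z_)
        if clamp_mode == "none":
            return lu
        s_c, _ = self.linear_scores(X, clamp=True)
        lc = _sigmoid(self.entropy_ + s_c - self.log_z_)
        if clamp_mode == "clamp":
            return lc
        return np.maximum(0.0, lc - np.abs(lc - lu))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class SuitabilityMap:
    """Raw (normalised Gibbs density), logistic suitability and clamp-flag
    grids over one projection area."""

    raw: Grid
    logistic: Grid
    clamp_flag: Grid

    def clamp_fraction(self) -> float:
        m = self.clamp_flag.mask()
        if not m.any():
            return 0.0
        return float(self.clamp_flag.values[m].mean())


def predict_map(model: MaxEnt, vs: VariableSet, clamp_mode: str = "none"
                ) -> SuitabilityMap:
    """Evaluate the model on every valid cell of a variable set.

    The raw output is re-normalised over the projection area (sums to 1);
    the logistic output uses the training entropy and partition value.
    """
    if clamp_mode not in CLAMP_MODES:
        raise ValueError(f"unknown clamp_mode {clamp_mode!r}")
    model._check_fitted()
    missing = [v for v in model.variables_ if v not in vs.layers]
    if missing:
        raise ValueError(f"variable set {vs.name!r} is missing model "
                         f"variables: {missing}")
    sub = vs.subset([v for v in vs.names() if v in model.variables_])
    mask = sub.valid_mask()
    ref = sub.ref_grid()
    rows, cols = np.nonzero(mask)
    X = pd.DataFrame({n: sub.layers[n].values[rows, cols] for n in sub.names()})

    s_u, flags = model.linear_scores(X, clamp=False)
    if clamp_mode == "none":
        s_eff = s_u
    else:
        s_c, flags = model.linear_scores(X, clamp=True)
        s_eff = s_c
    lu = _sigmoid(model.entropy_ + s_u - model.log_z_)
    if clamp_mode == "none":
        logistic = lu
    else:
        lc = _sigmoid(model.entropy_ + s_c - model.log_z_)
        logistic = lc if clamp_mode == "clamp" else np.maximum(0.0, lc - np.abs(lc - lu))

    raw = np.exp(s_eff - logsumexp(s_eff))

    nod = ref.nodata
    geo = dict(origin=ref.origin, cell_size=ref.cell_size, nodata=nod)
    raw_g = np.full(ref.shape, nod)
    log_g = np.full(ref.shape, nod)
    flag_g = np.full(ref.shape, nod)
    raw_g[rows, cols] = raw
    log_g[rows, cols] = logistic
    flag_g[rows, cols] = flags.astype(float)
    return SuitabilityMap(
        raw=Grid(raw_g, kind=CONTINUOUS, **geo),
        logistic=Grid(log_g, kind=CONTINUOUS, **geo),
        clamp_flag=Grid(flag_g, kind="categorical", **geo))


def mean_map(maps: list[SuitabilityMap]) -> SuitabilityMap:
    """Cellwise mean of replicate maps (raw, logistic and clamp share)."""
    if not maps:
        raise ValueError("no maps to average")
    ref = maps[0].logistic
    mask = ref.mask()
    for m in maps[1:]:
        mask &= m.logistic.mask()
    nod = ref.nodata
    geo = dict(origin=ref.origin, cell_size=ref.cell_size, nodata=nod)

    def avg(attr):
        acc = np.zeros(ref.shape)
        for m in maps:
            acc += np.where(mask, getattr(m, attr).values, 0.0)
        acc /= len(maps)
        return np.where(mask, acc, nod)

    return SuitabilityMap(
        raw=Grid(avg("raw"), kind=CONTINUOUS, **geo),
        logistic=Grid(avg("logistic"), kind=CONTINUOUS, **geo),
        clamp_flag=Grid(np.where(mask, avg("clamp_flag"), nod),
                        kind=CONTINUOUS, **geo))


@dataclass
class ReplicateResults:
    """Per-replicate models and metrics plus the aggregate mean map."""

    models: list[MaxEnt]
    metrics: pd.DataFrame            # one row per replicate
    mean_map: SuitabilityMap
    replicate_data: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "auc_train_mean": float(self.metrics["auc_train"].mean()),
            "auc_train_sd": float(self.metrics["auc_train"].std(ddof=0)),
            "auc_test_mean": float(self.metrics["auc_test"].mean()),
            "auc_test_sd": float(self.metrics["auc_test"].std(ddof=0)),
        }


def run_replicates(vs: VariableSet, presences: OccurrenceSet,
                   n_rep: int = 25, frac: float = 0.75,
                   n_background: int = 10_000, reg_beta: float = 1.0,
                   tol: float = 1e-6, max_iter: int = 5000,
                   master_seed: int = 0, compute_maps: bool = True,
                   keep_data: bool = False) -> ReplicateResults:
    """Bootstrap-replicate the model: split presences 75/25, draw a fresh
    background per replicate, fit, score train/test AUC, and average the
    replicate suitability maps."""
    from .evaluation import auc  # local import avoids a module cycle

    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    cat = vs.categorical_names()
    models: list[MaxEnt] = []
    rows = []
    maps: list[SuitabilityMap] = []
    data: list[dict] = []
    for rep in range(n_rep):
        try:
            train, test = bootstrap_split(
                presences, frac=frac, seed=subseed(master_seed, 1, rep))
            bg = sample_background(vs, n=n_background,
                                   seed=subseed(master_seed, 2, rep))
            X_train = extract_point_values(vs, train)
            X_test = extract_point_values(vs, test)
            X_bg = vs.extract(bg.points).dropna().reset_index(drop=True)
            X = pd.concat([X_train, X_bg], ignore_index=True)
            y = np.r_[np.ones(len(X_train)), np.zeros(len(X_bg))]
            model = MaxEnt(categorical=cat, reg_beta=reg_beta,
                           tol=tol, max_iter=max_iter)
            model.fit(X, y)
            model.train_grain_ = vs.grain
        except Exception as exc:
            raise RuntimeError(f"replicate {rep} failed: {exc}") from exc
        sc_bg = model.predict_logistic(X_bg)
        sc_train = model.predict_logistic(X_train)
        sc_test = model.predict_logistic(X_test)
        rows.append({
            "replicate": rep,
            "n_train": len(X_train), "n_test": len(X_test),
            "auc_train": auc(sc_train, sc_bg),
            "auc_test": auc(sc_test, sc_bg),
            "gain": model.gain_, "n_iter": model.n_iter_,
            "converged": model.converged_,
        })
        models.append(model)
        if compute_maps:
            maps.append(predict_map(model, vs, clamp_mode="none"))
        if keep_data:
            data.append({"X_train": X_train, "X_bg": X_bg, "bg": bg,
                         "train": train, "test": test})
    metrics = pd.DataFrame(rows)
    agg = mean_map(maps) if maps else None
    return ReplicateResults(models=models, metrics=metrics, mean_map=agg,
                            replicate_data=data)


# -- serialization ----------------------------------------------------------

def save_model(model: MaxEnt, path) -> None:
    """Plain-text model file: one JSON run header line, then one line per
    feature with ``name  lambda  clamp_min  clamp_max  mean  std``."""
    model._check_fitted()
    header = {
        "variables": model.variables_,
        "categorical": list(model.categorical),
        "classes": {k: v for k, v in model.classes_.items()},
        "quadratic": model.quadratic,
        "standardize": model.standardize,
        "reg_beta": model.reg_beta,
        "log_z": model.log_z_,
        "entropy": model.entropy_,
        "gain": model.gain_,
        "n_presences": model.n_presences_,
        "n_background": model.n_background_,
        "background_means": {k: float(v)
                             for k, v in model.background_means_.items()},
        "modal_class": model.modal_class_,
        "train_grain": getattr(model, "train_grain_", None),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for name in model.feature_names_:
            fh.write("\t".join([
                name,
                f"{model.lambdas_[name]:.17g}",
                f"{model.clamp_min_[name]:.17g}",
                f"{model.clamp_max_[name]:.17g}",
                f"{model.mean_[name]:.17g}",
                f"{model.std_[name]:.17g}",
            ]) + "\n")


def load_model(path) -> MaxEnt:
    with open(path) as fh:
        header = json.loads(fh.readline())
        names, lam, lo, hi, mu, sd = [], [], [], [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                continue
            names.append(parts[0])
            lam.append(float(parts[1]))
            lo.append(float(parts[2]))
            hi.append(float(parts[3]))
            mu.append(float(parts[4]))
            sd.append(float(parts[5]))
    model = MaxEnt(categorical=tuple(header["categorical"]),
                   quadratic=header["quadratic"],
                   standardize=header["standardize"],
                   reg_beta=header["reg_beta"])
    model.variables_ = list(header["variables"])
    model.classes_ = {k: [int(c) for c in v]
                      for k, v in header["classes"].items()}
    model.feature_names_ = names
    model.lambdas_ = pd.Series(lam, index=names)
    model.clamp_min_ = pd.Series(lo, index=names)
    model.clamp_max_ = pd.Series(hi, index=names)
    model.mean_ = pd.Series(mu, index=names)
    model.std_ = pd.Series(sd, index=names)
    model.log_z_ = header["log_z"]
    model.entropy_ = header["entropy"]
    model.gain_ = header["gain"]
    model.n_presences_ = header["n_presences"]
    model.n_background_ = header["n_background"]
    model.background_means_ = pd.Series(header["background_means"])
    model.modal_class_ = {k: int(v) for k, v in header["modal_class"].items()}
    model.gain_trajectory_ = np.array([])
    model.n_iter_ = 0
    model.converged_ = True
    if header.get("train_grain") is not None:
        model.train_grain_ = header["train_grain"]
    return model
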