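"""Orchestrate the full grain-size study from one configuration.

The study: simulate a training and a topographically distinct transfer
landscape and a virtual habitat-specialist species; build the three
predictor variable sets (1 km with climate, 300 m and 50 m biophysical
only); screen collinearity; rarefy presences at each grain; fit bootstrap
replicates of the maximum-entropy model; evaluate train/test AUC and the
Boyce index in the training area; project to the transfer landscape with
fade-by-clamping and score the transfer Boyce index.

Everything is deterministic under ``master_seed``: each stage and
replicate derives its own seed through :func:`grainsdm.seeds.subseed`.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape as ls
from .evaluation import boyce, permutation_importance, response_curve
from .grid import write_ascii
from .maxent import run_replicates
from .occurrences import clean_and_rarefy, sample_background
from .seeds import subseed
from .transfer import transfer_and_score
from .variables import build_variable_sets, filter_variable_set, scenario_for_grain

log = logging.getLogger("grainsdm")


@dataclass
class StudyConfig:
    """All knobs of the three-scenario study, with their study defaults:
    10,000 background points, 25 replicates at a 75/25 split, convergence
    threshold 1e-6 within 5000 iterations, Pearson cutoff 0.70, grains of
    50 m, 300 m and 1 km."""

    landscape_train: ls.LandscapeParams = field(default_factory=ls.LandscapeParams)
    landscape_transfer: ls.LandscapeParams | None = None
    species: ls.SpeciesParams = field(default_factory=ls.SpeciesParams)
    grains: tuple[float, ...] = (50.0, 300.0, 1000.0)
    n_rep: int = 25
    train_frac: float = 0.75
    tol: float = 1e-6
    max_iter: int = 5000
    reg_beta: float = 1.0
    n_background: int = 10_000
    n_transfer_presences: int = 100
    pearson_cutoff: float = 0.70
    aspect_mode: str = "northness"
    boyce_mode: str = "continuous"
    nbins: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.grains = tuple(float(g) for g in self.grains)
        if list(self.grains) != sorted(self.grains):
            raise ValueError("grains must be ascending")
        native = self.landscape_train.cell_size
        for g in self.grains:
            if abs(round(g / native) * native - g) > 1e-6:
                raise ValueError(f"grain {g} is not a multiple of the native "
                                 f"grain {native}")
        for name in ("n_rep", "max_iter", "n_background",
                     "n_transfer_presences", "nbins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.landscape_transfer is None:
            self.landscape_transfer = ls.transfer_params(self.landscape_train)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("landscape_train", "landscape_transfer"):
            d[key]["extent_cells"] = list(d[key]["extent_cells"])
        d["grains"] = list(self.grains)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, typ in (("landscape_train", ls.LandscapeParams),
                         ("landscape_transfer", ls.LandscapeParams)):
            if d.get(key) is not None and not isinstance(d[key], typ):
                sub = dict(d[key])
                if "extent_cells" in sub:
                    sub["extent_cells"] = tuple(sub["extent_cells"])
                d[key] = typ(**sub)
        if d.get("species") is not None and not isinstance(d["species"], ls.SpeciesParams):
            d["species"] = ls.SpeciesParams(**d["species"])
        if "grains" in d:
            d["grains"] = tuple(d["grains"])
        return cls(**d)


@dataclass
class StudyReport:
    """Per-scenario metrics plus handles to the persisted artifacts."""

    metrics: pd.DataFrame
    importance: pd.DataFrame
    outdir: Path | None = None


def _setup_logging(outdir: Path | None) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [logging.StreamHandler(sys.stderr)]
    if outdir is not None:
        log.handlers.append(logging.FileHandler(outdir / "study.log", mode="w"))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)


def simulate_study_inputs(config: StudyConfig):
    """Generate both landscapes, the species truth surfaces and the raw
    presence sets, all seeded from the master seed."""
    seed = config.master_seed
    tr = dataclasses.replace(config.landscape_train, seed=subseed(seed, 10))
    xf = dataclasses.replace(config.landscape_transfer, seed=subseed(seed, 11))
    bundle_train = ls.generate_landscape(tr)
    bundle_transfer = ls.generate_landscape(xf)
    truth_train = ls.true_suitability(bundle_train, config.species)
    truth_transfer = ls.true_suitability(bundle_transfer, config.species)
    pres_train = ls.sample_presences(truth_train, config.species.n_presences,
                                     seed=subseed(seed, 12))
    pres_transfer = ls.sample_presences(truth_transfer,
                                        config.n_transfer_presences,
                                        seed=subseed(seed, 13))
    return (bundle_train, bundle_transfer, truth_train, truth_transfer,
            pres_train, pres_transfer)


def run_study(config: StudyConfig, outdir=None,
              compute_response_curves: bool = False) -> StudyReport:
    """Run the full study; optionally persist rasters, CSV tables and a
    log under ``outdir``."""
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "rasters").mkdir(exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
    _setup_logging(outdir)
    t0 = time.time()
    seed = config.master_seed

    log.info("simulating landscapes and virtual species (seed=%d)", seed)
    (bundle_train, bundle_transfer, truth_train, truth_transfer,
     pres_train, pres_transfer) = simulate_study_inputs(config)

    vsets_train = build_variable_sets(bundle_train, aspect_mode=config.aspect_mode)
    vsets_transfer = build_variable_sets(bundle_transfer,
                                         aspect_mode=config.aspect_mode)

    rows = []
    imp_rows = []
    for gi, grain in enumerate(config.grains):
        t_sc = time.time()
        vs = scenario_for_grain(vsets_train, grain)
        name = vs.name
        log.info("scenario %s (%.0f m): collinearity screen", name, grain)
        try:
            screen_pts = sample_background(vs, n=config.n_background,
                                           seed=subseed(seed, 20, gi))
            vs_f, report = filter_variable_set(vs, screen_pts,
                                               cutoff=config.pearson_cutoff)
            if outdir is not None:
                report.to_csv(outdir / f"{name}_correlations.csv")
            vs_t = scenario_for_grain(vsets_transfer, grain).subset(vs_f.names())

            rarefied = clean_and_rarefy(pres_train, vs_f.ref_grid())
            log.info("scenario %s: %d/%d presences after rarefaction; "
                     "dropped layers: %s", name, len(rarefied), len(pres_train),
                     [d[0] for d in report.dropped] or "none")

            reps = run_replicates(
                vs_f, rarefied, n_rep=config.n_rep, frac=config.train_frac,
                n_background=config.n_background, reg_beta=config.reg_beta,
                tol=config.tol, max_iter=config.max_iter,
                master_seed=subseed(seed, 30, gi), keep_data=True)

            bkw = {"mode": config.boyce_mode}
            if config.boyce_mode == "binned":
                bkw["nbins"] = config.nbins
            cbi_train = boyce(reps.mean_map, rarefied, **bkw).rho

            xfer = transfer_and_score(reps.models, vs_t, pres_transfer,
                                      boyce_mode=config.boyce_mode,
                                      nbins=config.nbins)

            d0 = reps.replicate_data[0]
            imp = permutation_importance(reps.models[0], d0["X_train"],
                                         d0["X_bg"],
                                         seed=subseed(seed, 40, gi))
        except Exception as exc:
            raise RuntimeError(f"stage scenario={name} failed: {exc}") from exc

        s = reps.summary()
        rows.append({
            "scenario": name, "grain_m": grain,
            "n_presences": len(rarefied),
            "n_layers": len(vs_f.names()),
            "auc_train": s["auc_train_mean"], "auc_train_sd": s["auc_train_sd"],
            "auc_test": s["auc_test_mean"], "auc_test_sd": s["auc_test_sd"],
            "cbi_train": cbi_train,
            "cbi_transfer": xfer.cbi_transfer,
            "clamp_fraction_transfer": xfer.clamp_fraction,
        })
        for var, pct in imp.items():
            imp_rows.append({"scenario": name, "variable": var,
                             "importance_pct": pct})
        if outdir is not None:
            write_ascii(reps.mean_map.logistic,
                        outdir / "rasters" / f"{name}_train_suitability.asc")
            write_ascii(xfer.mean_map.logistic,
                        outdir / "rasters" / f"{name}_transfer_suitability.asc")
            reps.metrics.to_csv(outdir / f"{name}_replicates.csv", index=False)
            xfer.boyce_curve.to_csv(outdir / f"{name}_transfer_boyce.csv")
            if compute_response_curves:
                for var in reps.models[0].variables_:
                    rc = response_curve(reps.models[0], var)
                    rc.to_csv(outdir / f"{name}_response_{var}.csv", index=False)
        log.info("scenario %s done in %.1f s: auc_test=%.3f cbi_transfer=%.3f",
                 name, time.time() - t_sc, s["auc_test_mean"], xfer.cbi_transfer)

    metrics = pd.DataFrame(rows)
    importance = pd.DataFrame(imp_rows)
    if outdir is not None:
        metrics.to_csv(outdir / "metrics.csv", index=False)
        importance.to_csv(outdir / "importance.csv", index=False)
    log.info("study finished in %.1f s", time.time() - t0)
    return StudyReport(metrics=metrics, importance=importance, outdir=outdir)
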