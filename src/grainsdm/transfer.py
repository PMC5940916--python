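"""Project replicate models onto a second landscape and score
transferability with the Continuous Boyce Index.

The transfer variable set must be built at the same grain and with the
same variables as the models' training set -- scoring across grains is a
hard error, never a silent resample.  Projection uses fade-by-clamping to
attenuate cells whose features lie outside the training range; the mean
replicate map is scored against independent transfer presences rarefied at
the active grain, exactly as training presences were.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import BoyceCurve, boyce
from .maxent import MaxEnt, SuitabilityMap, mean_map, predict_map
from .occurrences import OccurrenceSet, clean_and_rarefy
from .variables import VariableSet


@dataclass
class TransferResult:
    """Transferability score of one scenario on the transfer landscape."""

    grain: float
    mean_map: SuitabilityMap
    boyce_curve: BoyceCurve
    cbi_transfer: float
    clamp_fraction: float
    n_presences: int

    def __post_init__(self) -> None:
        if np.isfinite(self.cbi_transfer) and not -1 <= self.cbi_transfer <= 1:
            raise ValueError("cbi_transfer must lie in [-1, 1]")
        if not 0 <= self.clamp_fraction <= 1:
            raise ValueError("clamp_fraction must lie in [0, 1]")


def transfer_and_score(models: list[MaxEnt], transfer_vs: VariableSet,
                       transfer_presences: OccurrenceSet,
                       clamp_mode: str = "fade",
                       boyce_mode: str = "continuous",
                       nbins: int = 10) -> TransferResult:
    """Project each replicate model onto the transfer landscape, average
    the maps, and compute the Boyce index of the mean map against the
    (rarefied) transfer presences."""
    if not models:
        raise ValueError("no models to transfer")
    for i, m in enumerate(models):
        grain = getattr(m, "train_grain_", None)
        if grain is not None and abs(grain - transfer_vs.grain) > 1e-9:
            raise ValueError(
                f"grain mismatch: model {i} was trained at {grain} m but the "
                f"transfer set is at {transfer_vs.grain} m; resample is never "
                f"implicit")
        missing = [v for v in m.variables_ if v not in transfer_vs.layers]
        extra = [v for v in transfer_vs.names() if v not in m.variables_]
        if missing:
            raise ValueError(
                f"variable mismatch between model {i} and transfer set: "
                f"missing {missing}, extra {extra}")

    rarefied = clean_and_rarefy(transfer_presences, transfer_vs.ref_grid())
    maps = [predict_map(m, transfer_vs, clamp_mode=clamp_mode) for m in models]
    agg = mean_map(maps)
    clamp_frac = float(np.mean([m.clamp_fraction() for m in maps]))
    kwargs = {"mode": boyce_mode}
    if boyce_mode == "binned":
        kwargs["nbins"] = nbins
    curve = boyce(agg, rarefied, **kwargs)
    return TransferResult(grain=transfer_vs.grain, mean_map=agg,
                          boyce_curve=curve, cbi_transfer=curve.rho,
                          clamp_fraction=clamp_frac,
                          n_presences=len(rarefied))
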