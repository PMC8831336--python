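"""Scan-level contrast-phase calls from per-slice probabilities.

Two aggregators are provided and both are always computed:

* ``mean`` — average the per-slice probability triples and take the argmax
  (the default: smoother, uses the full calibration information);
* ``majority`` — take each slice's argmax first, then the modal class, with
  ties broken by the higher mean probability and finally by the fixed class
  order NE < AR < PV.

The two can disagree (e.g. four slices mildly favouring AR vs three slices
strongly favouring PV); the disagreement is flagged per scan in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import PHASES
from .errors import AggregationError

AGGREGATION_MODES = ("mean", "majority")


@dataclass
class PhasePrediction:
    """Aggregated scan-level phase call plus the per-slice evidence."""

    scan_id: str
    slice_probs: np.ndarray  # (n_slices, 3) over (NE, AR, PV)
    levels: list[str] = field(default_factory=list)
    aggregated: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phase_call: str = "NE"
    mode: str = "mean"

    @property
    def n_slices_used(self) -> int:
        return int(self.slice_probs.shape[0])


def _check_probs(per_slice_probs) -> np.ndarray:
    p = np.asarray(per_slice_probs, dtype=float)
    if p.size == 0:
        raise AggregationError("cannot aggregate an empty set of slice predictions")
    if p.ndim == 1:
        p = p[None, :]
    if p.ndim != 2 or p.shape[1] != 3:
        raise AggregationError(f"expected (n, 3) probabilities, got shape {p.shape}")
    if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6):
        raise AggregationError("slice probabilities must lie on the 3-class simplex")
    return p


def aggregate_mean(per_slice_probs, scan_id: str = "", levels=None) -> PhasePrediction:
    """Mean of the slice probability triples; call = argmax (ties: NE<AR<PV)."""
    p = _check_probs(per_slice_probs)
    agg = p.mean(axis=0)
    call = PHASES[int(np.argmax(agg))]  # argmax takes the first maximum: NE<AR<PV
    return PhasePrediction(scan_id=scan_id, slice_probs=p, levels=list(levels or []),
                           aggregated=agg, phase_call=call, mode="mean")


def aggregate_majority(per_slice_probs, scan_id: str = "", levels=None) -> PhasePrediction:
    """Majority vote of per-slice argmax calls.

    Ties in the vote count are broken by the higher mean probability among
    the tied classes, then by the fixed class order NE < AR < PV.
    """
    p = _check_probs(per_slice_probs)
    votes = np.bincount(p.argmax(axis=1), minlength=3)
    mean_p = p.mean(axis=0)
    top = votes.max()
    tied = np.flatnonzero(votes == top)
    if len(tied) > 1:
        best = tied[np.argmax(mean_p[tied])]  # argmax again breaks exact ties NE<AR<PV
    else:
        best = tied[0]
    return PhasePrediction(scan_id=scan_id, slice_probs=p, levels=list(levels or []),
                           aggregated=mean_p, phase_call=PHASES[int(best)],
                           mode="majority")


def aggregate(per_slice_probs, mode: str = "mean", scan_id: str = "", levels=None) -> PhasePrediction:
    if mode == "mean":
        return aggregate_mean(per_slice_probs, scan_id, levels)
    if mode == "majority":
        return aggregate_majority(per_slice_probs, scan_id, levels)
    raise AggregationError(f"unknown aggregation mode {mode!r}")


def modes_disagree(per_slice_probs) -> bool:
    """True when the mean and majority aggregators call different phases."""
    p = _check_probs(per_slice_probs)
    return aggregate_mean(p).phase_call != aggregate_majority(p).phase_call
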