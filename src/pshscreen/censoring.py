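"""Censoring-distribution estimation and Fine-Gray risk-set weights.

The Fine-Gray partial likelihood keeps subjects in the cause-1 risk set
after a competing event, down-weighting them by how much longer they
could plausibly have remained under observation.  Both ingredients live
here: the Kaplan-Meier estimate of the censoring survival
G(t) = Pr(C >= t) (censoring is the "event"; failures of any cause are
treated as censored observations of C), and the weight schedule

    w_i(t) = I(C_i >= Y_i ^ t) * G(t) / G(Y_i ^ t).

Conventions: G is evaluated left-continuously, so the drop caused by a
censoring at time t takes effect strictly after t, and at tied times
failures precede censorings (a subject failing at t still counts as at
risk for censoring at t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CompetingRisksDataset
from .stepfun import StepFunction

__all__ = ["km_censoring", "fg_weights", "FGWeightSchedule", "km_survival"]


def km_censoring(data: CompetingRisksDataset) -> StepFunction:
    """Kaplan-Meier estimate of the censoring survival G(t) = Pr(C >= t).

    Returned as a left-continuous :class:`StepFunction`: G(t) includes
    censorings strictly before t only, so G(Y_i) is well defined and
    positive for every observed subject.
    """
    time = np.asarray(data.time, float)
    censored = data.cause == 0
    cens_times = np.unique(time[censored])
    if cens_times.size == 0:
        return StepFunction.constant(1.0, continuity="left")
    # ties: failures precede censorings, so everyone with Y >= t is at risk
    n_at_risk = np.array([(time >= t).sum() for t in cens_times], dtype=float)
    d = np.array([((time == t) & censored).sum() for t in cens_times], dtype=float)
    surv = np.cumprod(1.0 - d / n_at_risk)
    return StepFunction(cens_times, surv, initial_value=1.0, continuity="left")


def km_survival(time, event, *, continuity: str = "right") -> StepFunction:
    """Plain Kaplan-Meier survival of an event indicator (right-continuous)."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    etimes = np.unique(time[event])
    if etimes.size == 0:
        return StepFunction.constant(1.0, continuity=continuity)
    n_at_risk = np.array([(time >= t).sum() for t in etimes], dtype=float)
    d = np.array([((time == t) & event).sum() for t in etimes], dtype=float)
    surv = np.cumprod(1.0 - d / n_at_risk)
    return StepFunction(etimes, surv, initial_value=1.0, continuity=continuity)


@dataclass
class FGWeightSchedule:
    """Per-subject Fine-Gray weights w_i(.) as functions of time.

    ``weight_matrix(times)`` is the workhorse: an (n, len(times)) array of
    w_i(t).  Subjects are also removable from the risk set via
    ``risk_matrix``; the product of the two is what the partial
    likelihood consumes.
    """

    data: CompetingRisksDataset
    G: StepFunction
    #: subjects whose weight was forced to 0 because G(Y_i) = 0
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        G_at_Y = np.atleast_1d(self.G(self.data.time))
        bad = (G_at_Y <= 0.0) & (self.data.cause >= 2)
        self.degenerate = np.flatnonzero(bad)
        self._G_at_Y = np.where(G_at_Y > 0, G_at_Y, np.inf)

    def weight_matrix(self, times) -> np.ndarray:
        """w_i(t) for every subject i (rows) and query time t (columns)."""
        times = np.atleast_1d(np.asarray(times, float))
        Y = self.data.time[:, None]
        cause = self.data.cause[:, None]
        G_t = np.atleast_1d(self.G(times))[None, :]
        ratio = G_t / self._G_at_Y[:, None]
        w = np.where(times[None, :] <= Y, 1.0, np.where(cause == 0, 0.0, ratio))
        return w

    def risk_matrix(self, times) -> np.ndarray:
        """R_i(t) = 1 - N_i(t-): cause-1 failures leave the risk set."""
        times = np.atleast_1d(np.asarray(times, float))
        Y = self.data.time[:, None]
        cause = self.data.cause[:, None]
        return 1.0 - ((Y < times[None, :]) & (cause == 1)).astype(float)

    def __call__(self, times) -> np.ndarray:
        return self.weight_matrix(times)

    def subject_weight(self, i: int) -> StepFunction:
        """w_i(.) as an explicit step function (for export/inspection)."""
        jumps = self.G.jump_times[self.G.jump_times > self.data.time[i]]
        grid = np.concatenate([[self.data.time[i]], jumps])
        # value just after each grid point
        eps = np.concatenate([np.diff(grid), [1.0]])
        vals = self.weight_matrix(grid + np.minimum(eps, 1.0) * 0.5)[i]
        return StepFunction(grid, vals, initial_value=1.0, continuity="right")


def fg_weights(data: CompetingRisksDataset, G: StepFunction | None = None) -> FGWeightSchedule:
    """Fine-Gray weight schedule for ``data`` under censoring survival ``G``.

    ``G`` defaults to :func:`km_censoring` on the same data; pass a
    training-cohort estimate to weight held-out data consistently.
    """
    if G is None:
        G = km_censoring(data)
    return FGWeightSchedule(data, G)
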