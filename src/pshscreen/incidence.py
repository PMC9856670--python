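"""Nonparametric cumulative incidence, Gray's K-sample test, and
median-cutoff risk stratification.

The Aalen-Johansen estimator generalises Kaplan-Meier to competing
risks: with all-cause survival S estimated by product limit, the cause-k
CIF accumulates S(t-) d_k(t)/n(t) at each event time, so that at every
event time the cause-specific incidences and the survival add to one.

Gray's test compares the cause-1 CIF across K groups through a weighted
log-rank score over *subdistribution* risk sets: subjects who failed
from a competing cause remain at risk, carried with inverse-censoring
weights G(t)/G(Y_i) built from the pooled censoring Kaplan-Meier (the
IPCW formulation of the test; the weighted risk set equals the classical
(1 - F1(t-))/S(t-)-retained one by the product-limit identity).  The
score's variance is estimated from per-subject influence terms, with the
correction for the estimated censoring curve entering through the
censoring martingale; the statistic score' V^- score is referred to a
chi-square with K-1 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._partial_likelihood import FGDesign
from .data import CompetingRisksDataset
from .stepfun import StepFunction

__all__ = [
    "CIFEstimate",
    "GrayTestResult",
    "RiskStratification",
    "aalen_johansen",
    "gray_test",
    "stratify",
]


@dataclass
class CIFEstimate:
    """Aalen-Johansen CIFs per cause plus the all-cause KM survival."""

    cif: dict  # cause code -> StepFunction
    survival: StepFunction
    group_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cause, fn in sorted(self.cif.items()):
            for t, v in zip(fn.jump_times, fn.values):
                rows.append({"group": self.group_label, "cause": cause, "time": t, "cif": v})
        return pd.DataFrame(rows, columns=["group", "cause", "time", "cif"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GrayTestResult:
    statistic: float
    df: int
    p_value: float

    def summary_line(self) -> str:
        return f"statistic={self.statistic:.6g}\tdf={self.df}\tp={self.p_value:.6g}"


@dataclass
class RiskStratification:
    risk_score: np.ndarray  # train scores then test scores
    cutoff: float
    group: np.ndarray  # 'high'/'low' labels, train then test
    n_train: int
    imbalanced: bool = False

    @property
    def train_group(self) -> np.ndarray:
        return self.group[: self.n_train]

    @property
    def test_group(self) -> np.ndarray:
        return self.group[self.n_train :]


def aalen_johansen(data: CompetingRisksDataset) -> CIFEstimate:
    """Aalen-Johansen CIF estimate for every observed cause."""
    time = data.time
    cause = data.cause
    event_times = np.unique(time[cause >= 1])
    causes = sorted(int(c) for c in np.unique(cause) if c >= 1)
    if event_times.size == 0:
        return CIFEstimate(
            {1: StepFunction.constant(0.0)}, StepFunction.constant(1.0), ""
        )
    n_at_risk = np.array([(time >= t).sum() for t in event_times], dtype=float)
    d_all = np.array([((time == t) & (cause >= 1)).sum() for t in event_times], dtype=float)
    surv_after = np.cumprod(1.0 - d_all / n_at_risk)
    surv_before = np.concatenate([[1.0], surv_after[:-1]])
    cif = {}
    for c in causes:
        d_c = np.array([((time == t) & (cause == c)).sum() for t in event_times], dtype=float)
        cif[c] = StepFunction(
            event_times,
            np.cumsum(surv_before * d_c / n_at_risk),
            initial_value=0.0,
            continuity="right",
        )
    return CIFEstimate(cif, StepFunction(event_times, surv_after, 1.0, "right"))


def gray_test(data: CompetingRisksDataset, group) -> GrayTestResult:
    """Gray's K-sample test for equality of cause-1 CIFs (rho = 0)."""
    group = np.asarray(group)
    labels, gidx = np.unique(group, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("need at least 2 groups")
    if len(group) != data.n:
        raise ValueError("group labels must match the number of subjects")

    design = FGDesign(data)  # pooled censoring KM, pooled cause-1 event times
    if design.n_events == 0:
        raise ValueError("no cause-1 events")
    A = design.A  # (n, T) weighted subdistribution risk sets
    t_events = design.event_times
    T = t_events.size
    onehot = np.zeros((data.n, K))
    onehot[np.arange(data.n), gidx] = 1.0

    h = onehot.T @ A  # (K, T) group weighted risk sets
    h_tot = h.sum(axis=0)
    dN1 = np.zeros((data.n, T))
    ev = data.cause == 1
    dN1[ev, np.searchsorted(t_events, data.time[ev])] = 1.0
    dN1_g = onehot.T @ dN1  # (K, T)
    dN1_tot = dN1_g.sum(axis=0)
    P = h / h_tot  # expected share of events per group
    z = (dN1_g - P * dN1_tot).sum(axis=1)
    dLam = dN1_tot / h_tot

    # per-subject influence: martingale residual part
    D = dN1 - A * dLam  # (n, T)
    eta = onehot * D.sum(axis=1)[:, None] - D @ P.T  # (n, K)

    # censoring-martingale correction for the estimated weights
    psi = np.zeros((data.n, K))
    cens = data.cause == 0
    cens_times = np.unique(data.time[cens])
    for u in cens_times:
        at_risk = data.time >= u
        Yu = float(at_risk.sum())
        dNc = ((data.time == u) & cens).astype(float)
        dLc = dNc.sum() / Yu
        late = t_events >= u  # event times the perturbation reaches
        if late.any():
            before = (data.time < u).astype(float)
            M = (before[:, None] * A[:, late]) * dLam[late][None, :]  # (n, T_late)
            q = onehot.T @ M.sum(axis=1) - (P[:, late] * M.sum(axis=0)[None, :]).sum(axis=1)
        else:
            q = np.zeros(K)
        psi += np.outer((dNc - at_risk * dLc) / Yu, q)

    infl = eta + psi
    V = infl.T @ infl
    stat = float(z @ np.linalg.pinv(V, rcond=1e-10) @ z)
    stat = max(stat, 0.0)
    df = K - 1
    return GrayTestResult(stat, df, float(stats.chi2.sf(stat, df)))


def stratify(train_scores, test_scores=None) -> RiskStratification:
    """Median-cutoff high/low risk grouping.

    The cutoff is the training median (midpoint of the central order
    statistics for even counts); scores strictly above it are high risk.
    The frozen cutoff is applied unchanged to the test scores.
    """
    train_scores = np.asarray(train_scores, float)
    if train_scores.size == 0:
        raise ValueError("train_scores must be non-empty")
    if np.unique(train_scores).size == 1:
        raise ValueError("all training scores identical: no stratification possible")
    test_scores = np.asarray(test_scores, float) if test_scores is not None else np.empty(0)
    cutoff = float(np.median(train_scores))
    scores = np.concatenate([train_scores, test_scores])
    group = np.where(scores > cutoff, "high", "low")
    n_hi = int((train_scores > cutoff).sum())
    imbalanced = abs(n_hi - (len(train_scores) - n_hi)) > 1
    if imbalanced:
        warnings.warn(
            f"degenerate median: training groups of sizes "
            f"{len(train_scores) - n_hi}/{n_hi} are imbalanced"
        )
    return RiskStratification(scores, cutoff, group, len(train_scores), imbalanced)
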