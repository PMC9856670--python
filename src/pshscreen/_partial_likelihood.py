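"""Weighted Fine-Gray partial-likelihood kernel.

Everything upstream (plain PSH fits, per-feature screening fits,
component-wise boosting, cross-validated path evaluation) reduces to a
handful of quantities defined on the cause-1 event times t_1 < ... < t_K:

    A[j, k] = w_j(t_k) * R_j(t_k)      (weighted risk-set membership)
    S0_k    = sum_j A[j, k] exp(eta_j)
    S1_k    = sum_j A[j, k] exp(eta_j) v_j
    ...

A depends on the data and the censoring survival only — not on the
coefficients — so it is precomputed once per dataset (``FGDesign``) and
shared across the thousands of small Newton fits screening performs.
Event-time ties are handled with the Breslow convention (shared
denominator).
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

from .censoring import FGWeightSchedule, km_censoring
from .stepfun import StepFunction

__all__ = ["FGDesign", "newton_fit", "SingularInformation", "Separation"]


class SingularInformation(np.linalg.LinAlgError):
    """Information matrix singular; carries the offending column indices."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = columns or []


class Separation(RuntimeError):
    """Monotone likelihood: a coefficient diverges."""


class FGDesign:
    """Precomputed risk-set weights of a dataset at its cause-1 event times."""

    def __init__(self, data, G=None):
        self.data = data
        if G is None:
            G = km_censoring(data)
        self.G = G
        self.weights = FGWeightSchedule(data, G)

        cause1 = data.cause == 1
        self.event_rows = np.flatnonzero(cause1)
        self.event_times = np.unique(data.time[cause1])  # t_1 < ... < t_K
        K = self.event_times.size
        if K:
            self.d = np.array(
                [np.sum(cause1 & (data.time == t)) for t in self.event_times], dtype=float
            )
            self.A = self.weights.weight_matrix(self.event_times) * self.weights.risk_matrix(
                self.event_times
            )
        else:
            self.d = np.zeros(0)
            self.A = np.zeros((data.n, 0))
        self.n_events = int(self.d.sum())

    # -- likelihood pieces -------------------------------------------------
    def loglik(self, V, theta, offset=None):
        """l_n at coefficients ``theta`` for covariate matrix ``V`` (n, q)."""
        if self.event_times.size == 0:
            return 0.0
        eta = V @ np.asarray(theta, float) if V.shape[1] else np.zeros(V.shape[0])
        if offset is not None:
            eta = eta + offset
        m = eta.max() if eta.size else 0.0
        e = np.exp(eta - m)
        S0 = self.A.T @ e
        return float(eta[self.event_rows].sum() - self.d @ (np.log(S0) + m))

    def score_information(self, V, theta, offset=None):
        """(loglik, score U, information -H) at ``theta``."""
        q = V.shape[1]
        if self.event_times.size == 0:
            return 0.0, np.zeros(q), np.zeros((q, q))
        eta = V @ np.asarray(theta, float) if q else np.zeros(V.shape[0])
        if offset is not None:
            eta = eta + offset
        m = eta.max()
        e = np.exp(eta - m)
        Ae = self.A * e[:, None]  # (n, K)
        S0 = Ae.sum(axis=0)  # (K,)
        S1 = V.T @ Ae  # (q, K)
        xbar = S1 / S0  # (q, K)
        ll = float(eta[self.event_rows].sum() - self.d @ (np.log(S0) + m))
        U = V[self.event_rows].sum(axis=0) - xbar @ self.d
        c = Ae @ (self.d / S0)  # (n,)
        B = xbar * np.sqrt(self.d)
        H = V.T @ (c[:, None] * V) - B @ B.T
        return ll, U, H

    def componentwise_updates(self, X, eta):
        """Per-column score U_j and curvature I_j of l_n at offset ``eta``.

        Used by boosting: for each candidate feature column of X (holding
        the current linear predictor fixed) the first and negative second
        derivative with respect to that column's coefficient alone.
        """
        if self.event_times.size == 0:
            raise ValueError("no cause-1 events: component-wise updates undefined")
        m = eta.max()
        e = np.exp(eta - m)
        Ae = self.A * e[:, None]
        S0 = Ae.sum(axis=0)
        c = Ae @ (self.d / S0)
        S1 = X.T @ Ae  # (p, K)
        xbar = S1 / S0
        U = X[self.event_rows].sum(axis=0) - xbar @ self.d
        I = (X * X).T @ c - (xbar * xbar) @ self.d
        return U, I

    def breslow(self, V, theta) -> StepFunction:
        """Breslow cumulative baseline subdistribution hazard (right-cont.)."""
        if self.event_times.size == 0:
            return StepFunction.constant(0.0)
        eta = V @ np.asarray(theta, float) if V.shape[1] else np.zeros(V.shape[0])
        S0 = self.A.T @ np.exp(eta)
        return StepFunction(
            self.event_times, np.cumsum(self.d / S0), initial_value=0.0, continuity="right"
        )


def _diagnose_collinear(V, names=None):
    _, r, piv = sla.qr(V, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(V.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [int(piv[i]) for i in range(len(diag)) if diag[i] <= tol]
    if names is not None:
        bad = [names[i] for i in bad]
    return bad


def newton_fit(
    design: FGDesign,
    V: np.ndarray,
    init=None,
    *,
    tol: float = 1e-9,
    max_iter: int = 100,
    names=None,
    divergence_bound: float = 30.0,
):
    """Maximise l_n over theta by Newton-Raphson with step-halving.

    Returns (theta, loglik, information, converged, n_iter).  Convergence:
    relative log-likelihood change below ``tol``.  A coefficient whose
    standardised magnitude exceeds ``divergence_bound`` marks monotone
    likelihood (separation) and the fit is flagged unconverged.
    """
    n, q = V.shape
    theta = np.zeros(q) if init is None else np.array(init, float)
    if q == 0 or design.event_times.size == 0:
        ll = design.loglik(V, theta)
        return theta, ll, np.zeros((q, q)), True, 0
    scale = V.std(axis=0)
    scale[scale == 0] = 1.0

    ll, U, H = design.score_information(V, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            cho = sla.cho_factor(H)
            step = sla.cho_solve(cho, U)
        except (sla.LinAlgError, ValueError):
            bad = _diagnose_collinear(V, names)
            raise SingularInformation(
                f"singular information matrix; collinear/constant columns: {bad}", bad
            )
        size = 1.0
        for _ in range(40):
            cand = theta + size * step
            ll_new = design.loglik(V, cand)
            if ll_new >= ll - 1e-12:
                break
            size /= 2.0
        theta = theta + size * step
        ll_prev, ll = ll, ll_new
        if abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-10):
            converged = True
            break
        ll, U, H = design.score_information(V, theta)
        if np.any(np.abs(theta * scale) > divergence_bound):
            converged = False
            break
    ll, U, H = design.score_information(V, theta)
    if np.any(np.abs(theta * scale) > divergence_bound):
        converged = False
    return theta, ll, H, converged, it
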