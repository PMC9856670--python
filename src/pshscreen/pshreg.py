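"""Fine-Gray proportional subdistribution hazards (PSH) regression.

The subdistribution hazard of the event of interest (cause 1),

    lambda_1(t; x, z) = lambda_10(t) exp(beta'x + gamma'z),

is the instantaneous cause-1 failure rate among subjects who have not yet
failed from cause 1 — a risk set that keeps subjects after censoring or a
competing event, with Kaplan-Meier-of-censoring weights (module
``censoring``).  Coefficients maximise the weighted log partial
likelihood; the cumulative baseline hazard H_10 is the Breslow step
estimator; the cumulative incidence function follows as

    F_1(t | x, z) = 1 - exp(-H_10(t) exp(beta'x + gamma'z)).

``FineGrayPSH`` is the scikit-learn style estimator; :func:`psh_fit` and
friends are thin wrappers operating on a :class:`CompetingRisksDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from ._partial_likelihood import FGDesign, newton_fit
from .censoring import km_censoring
from .data import CRISK_DTYPE, CompetingRisksDataset, crisk_target
from .stepfun import StepFunction

__all__ = ["FineGrayPSH", "PSHFit", "psh_loglik", "psh_fit", "predict_cif"]


def _check_crisk_y(y):
    y = np.asarray(y)
    if y.dtype.names is None or set(y.dtype.names) != {"cause", "time"}:
        raise ValueError(
            "y must be a structured array with fields ('cause', 'time'); "
            "build one with pshscreen.crisk_target(time, cause)"
        )
    return y.astype(CRISK_DTYPE, copy=False)


class FineGrayPSH(BaseEstimator):
    """Fine-Gray PSH regression estimator (scikit-learn interface).

    Parameters
    ----------
    tol : float
        Relative log-partial-likelihood convergence tolerance of the
        Newton-Raphson solver.
    max_iter : int
        Newton iteration cap; hitting it leaves ``converged_`` False.

    Attributes
    ----------
    coef_ : ndarray (n_features,)
        Log subdistribution hazard ratios.
    loglik_ : float
        Maximised weighted log partial likelihood.
    info_matrix_ : ndarray
        Negative Hessian at the optimum (naive information; the full
        Fine-Gray sandwich accounting for the estimated censoring curve
        is deliberately not computed).
    baseline_cumhazard_ : StepFunction
        Breslow estimate of H_10 with jumps at cause-1 event times.
    censoring_survival_ : StepFunction
        Kaplan-Meier estimate of Pr(C >= t) used for the weights.
    """

    def __init__(self, *, tol: float = 1e-9, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, *, init=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        y = _check_crisk_y(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        data = _as_dataset(X, y)
        design = FGDesign(data)
        n_events = design.n_events
        if X.shape[1] >= max(n_events, 1):
            raise ValueError(
                f"{X.shape[1]} coefficients but only {n_events} cause-1 events; "
                "the partial likelihood is not identifiable"
            )
        const = np.flatnonzero(X.std(axis=0) == 0)
        if const.size:
            raise ValueError(f"constant covariate columns: {const.tolist()}")
        theta, ll, info, converged, n_iter = newton_fit(
            design, X, init, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_ = theta
        self.loglik_ = ll
        self.info_matrix_ = info
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.baseline_cumhazard_ = design.breslow(X, theta)
        self.censoring_survival_ = design.G
        self.n_features_in_ = X.shape[1]
        self._design = design
        return self

    # -- prediction --------------------------------------------------------
    def predict(self, X):
        """Linear predictor beta'x (the risk score)."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_

    def predict_cif(self, X, times):
        """Predicted cause-1 CIF, shape (n_subjects, n_times)."""
        check_is_fitted(self, "coef_")
        lp = self.predict(X)
        H = np.atleast_1d(self.baseline_cumhazard_(np.asarray(times, float)))
        return 1.0 - np.exp(-np.outer(np.exp(lp), H))

    def score(self, X, y):
        """Weighted log partial likelihood of ``coef_`` on new data
        (weights from the new data's own censoring curve)."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        y = _check_crisk_y(y)
        design = FGDesign(_as_dataset(X, y))
        return design.loglik(X, self.coef_)

    # -- inference ---------------------------------------------------------
    def covariance_(self):
        """Naive coefficient covariance: inverse information.

        Does not account for estimation of the censoring curve; labelled
        naive throughout.
        """
        check_is_fitted(self, "coef_")
        return np.linalg.inv(self.info_matrix_)

    def summary(self, names=None, conf_level: float = 0.95) -> pd.DataFrame:
        check_is_fitted(self, "coef_")
        se = np.sqrt(np.diag(self.covariance_()))
        z = stats.norm.ppf(0.5 + conf_level / 2)
        coef = self.coef_
        if names is None:
            names = [f"x{i}" for i in range(len(coef))]
        return pd.DataFrame(
            {
                "term": names,
                "coef": coef,
                "hazard_ratio": np.exp(coef),
                "naive_se": se,
                "ci_lower": np.exp(coef - z * se),
                "ci_upper": np.exp(coef + z * se),
                "p_value": 2 * stats.norm.sf(np.abs(coef) / se),
            }
        )


def _as_dataset(X, y) -> CompetingRisksDataset:
    n = len(y)
    return CompetingRisksDataset(
        subject_id=np.arange(n),
        time=y["time"],
        cause=y["cause"],
        X=pd.DataFrame(np.asarray(X, float)),
        Z=pd.DataFrame(index=range(n)),
    )


# ---------------------------------------------------------------------------
# Dataset-level wrappers


@dataclass
class PSHFit:
    """Fitted PSH model on a dataset: screened-feature coefficients
    ``beta``, control coefficients ``gamma``, and the Breslow baseline."""

    beta: np.ndarray
    gamma: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    info_matrix: np.ndarray
    baseline: StepFunction
    feature_names: list
    control_names: list
    censoring_survival: StepFunction = None

    @property
    def coef(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma])

    def linear_predictor(self, x, z) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float)) if len(self.beta) else None
        z = np.atleast_2d(np.asarray(z, float)) if len(self.gamma) else None
        lp = 0.0
        if x is not None:
            lp = lp + x @ self.beta
        if z is not None:
            lp = lp + z @ self.gamma
        return np.atleast_1d(lp)

    def summary(self) -> pd.DataFrame:
        est = FineGrayPSH.__new__(FineGrayPSH)
        est.coef_ = self.coef
        est.info_matrix_ = self.info_matrix
        return est.summary(names=list(self.feature_names) + list(self.control_names))

    def write_tsv(self, path) -> None:
        self.summary().to_csv(path, sep="\t", index=False)


def _design_matrix(data: CompetingRisksDataset, feature_subset):
    if feature_subset is None:
        feature_subset = list(range(data.p))
    feature_subset = list(feature_subset)
    Xs = data.X.iloc[:, feature_subset].to_numpy(dtype=float) if feature_subset else np.empty((data.n, 0))
    Z = data.Z.to_numpy(dtype=float) if data.p0 else np.empty((data.n, 0))
    V = np.hstack([Xs, Z])
    names = [data.feature_names[j] for j in feature_subset]
    return V, names, feature_subset


def psh_loglik(beta, gamma, data: CompetingRisksDataset, weights=None, feature_subset=None) -> float:
    """Weighted log partial likelihood l_n(beta, gamma) on ``data``."""
    V, _, subset = _design_matrix(data, feature_subset)
    beta = np.atleast_1d(np.asarray(beta, float)) if np.size(beta) else np.zeros(0)
    gamma = np.atleast_1d(np.asarray(gamma, float)) if np.size(gamma) else np.zeros(0)
    if len(beta) != len(subset) or len(gamma) != data.p0:
        raise ValueError("coefficient dimensions do not match X/Z")
    design = FGDesign(data, None if weights is None else weights.G)
    return design.loglik(V, np.concatenate([beta, gamma]))


def psh_fit(
    data: CompetingRisksDataset,
    feature_subset=None,
    *,
    init=None,
    G: StepFunction | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> PSHFit:
    """Newton-Raphson maximum weighted partial likelihood fit.

    ``feature_subset`` selects columns of X (all by default); Z is always
    included.  ``G`` overrides the censoring survival (e.g. a training
    estimate when refitting on a sub-cohort).
    """
    V, names, subset = _design_matrix(data, feature_subset)
    design = FGDesign(data, G)
    q = V.shape[1]
    if q >= max(design.n_events, 1):
        raise ValueError(
            f"{q} coefficients but only {design.n_events} cause-1 events; not identifiable"
        )
    const = np.flatnonzero(V.std(axis=0) == 0)
    if const.size:
        all_names = names + data.control_names
        raise ValueError(f"constant covariate columns: {[all_names[i] for i in const]}")
    theta, ll, info, converged, n_iter = newton_fit(
        design, V, init, tol=tol, max_iter=max_iter, names=names + data.control_names
    )
    k = len(subset)
    return PSHFit(
        beta=theta[:k],
        gamma=theta[k:],
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        info_matrix=info,
        baseline=design.breslow(V, theta),
        feature_names=names,
        control_names=data.control_names,
        censoring_survival=design.G,
    )


def predict_cif(fit: PSHFit, x, z, times) -> StepFunction:
    """Predicted cause-1 CIF for one subject as a step function."""
    lp = float(fit.linear_predictor(x, z)[0])
    times = np.unique(np.asarray(times, float))
    vals = 1.0 - np.exp(-np.atleast_1d(fit.baseline(times)) * np.exp(lp))
    keep = times > 0  # F1(0) = 0 is the initial value, not a jump
    return StepFunction(times[keep], vals[keep], initial_value=0.0, continuity="right")
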