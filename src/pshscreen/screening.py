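"""PSH-CSIS: conditional sure-independence screening for the PSH model.

With thousands of candidate features and a handful of mandatory clinical
controls Z, joint estimation is hopeless; screening instead fits, for
each feature X_j alone, the PSH model with covariates (X_j, Z) and scores
the feature by the maximised log partial likelihood

    u_j = max_{beta_j, gamma} l_n(beta_j, gamma).

Since max_gamma l_n(0, gamma) is a common constant, ranking by u_j ranks
features by the likelihood gain X_j offers *after adjusting for Z*.  The
top d features are recruited; the sure-screening property lets d be
generous (all truly active features retained with high probability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._partial_likelihood import FGDesign, SingularInformation, newton_fit
from .data import CompetingRisksDataset
from .pshreg import _check_crisk_y

__all__ = ["default_model_size", "psh_csis", "PSHScreener", "ScreeningResult"]

_SIZE_RULES = ("n_over_logn", "2n_over_logn", "3n_over_logn", "n_minus_p0_minus_1")


def default_model_size(n: int, p0: int, rule: str = "n_minus_p0_minus_1") -> int:
    """Conventional screening model sizes.

    ``n_over_logn`` and multiples use floor and the natural logarithm;
    ``n_minus_p0_minus_1`` leaves room for an intercept-free PSH fit with
    the p0 controls.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if rule == "n_minus_p0_minus_1":
        d = n - p0 - 1
    elif rule in _SIZE_RULES:
        mult = {"n_over_logn": 1, "2n_over_logn": 2, "3n_over_logn": 3}[rule]
        d = mult * int(np.floor(n / np.log(n)))
    else:
        raise ValueError(f"unknown rule {rule!r}; choose one of {_SIZE_RULES}")
    if d < 1:
        raise ValueError(f"model-size rule {rule!r} gives non-positive d={d} for n={n}, p0={p0}")
    return int(d)


class PSHScreener(SelectorMixin, BaseEstimator):
    """Feature screening transformer for competing-risks outcomes.

    The first ``n_mandatory`` columns of X are the controls Z: they are
    conditioned on during screening, never ranked, and always retained by
    :meth:`transform`.

    Parameters
    ----------
    d : int or None
        Number of features to recruit; ``None`` applies ``rule``.
    rule : str
        Model-size rule used when ``d`` is None (see
        :func:`default_model_size`).
    n_mandatory : int
        Leading columns of X treated as mandatory controls.
    """

    def __init__(self, d=None, rule: str = "n_minus_p0_minus_1", n_mandatory: int = 0):
        self.d = d
        self.rule = rule
        self.n_mandatory = n_mandatory

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = _check_crisk_y(y)
        n, total = X.shape
        m = int(self.n_mandatory)
        if not 0 <= m < total:
            raise ValueError("n_mandatory out of range")
        p = total - m
        d = self.d if self.d is not None else default_model_size(n, m, self.rule)
        if not 1 <= d <= p:
            raise ValueError(f"model size d={d} outside 1..{p}")

        from .pshreg import _as_dataset  # deferred: avoids import cycle

        design = FGDesign(_as_dataset(X, y))
        if design.n_events == 0:
            raise ValueError("no cause-1 events: screening undefined")
        Z = X[:, :m]
        gamma0, null_ll, _, _, _ = newton_fit(design, Z)

        u = np.full(p, null_ll)
        ok = np.zeros(p, dtype=bool)
        V = np.empty((n, m + 1))
        V[:, 1:] = Z
        init = np.concatenate([[0.0], gamma0])
        for j in range(p):
            V[:, 0] = X[:, m + j]
            if V[:, 0].std() == 0.0:
                continue
            try:
                _, ll_j, _, conv, _ = newton_fit(design, V, init)
            except SingularInformation:
                continue
            if conv:
                # guard tiny negative slack from finite tolerance
                u[j] = max(ll_j, null_ll)
                ok[j] = True

        order = np.lexsort((np.arange(p), -u))  # descending u, ties by index
        rank = np.empty(p, dtype=int)
        rank[order] = np.arange(1, p + 1)
        self.u_ = u
        self.null_loglik_ = null_ll
        self.rank_ = rank
        self.converged_ = ok
        self.d_ = int(d)
        self.selected_ = np.sort(order[:d])
        self.n_features_in_ = total
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[: self.n_mandatory] = True
        mask[self.n_mandatory + self.selected_] = True
        return mask


@dataclass
class ScreeningResult:
    """Per-feature screening scores and the recruited set."""

    u: np.ndarray
    rank: np.ndarray
    selected: np.ndarray
    d: int
    null_loglik: float
    converged: np.ndarray
    feature_names: list

    def to_frame(self) -> pd.DataFrame:
        sel = np.zeros(len(self.u), dtype=bool)
        sel[self.selected] = True
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "u": self.u,
                "delta_loglik": self.u - self.null_loglik,
                "rank": self.rank,
                "selected": sel,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def psh_csis(data: CompetingRisksDataset, d: int | None = None) -> ScreeningResult:
    """Run PSH-CSIS on a dataset; ``d`` defaults to n - p0 - 1."""
    if d is None:
        d = default_model_size(data.n, data.p0, "n_minus_p0_minus_1")
    if d > data.p:
        raise ValueError(f"d={d} exceeds number of features p={data.p}")
    X = np.hstack([data.Z.to_numpy(dtype=float), data.X.to_numpy(dtype=float)])
    scr = PSHScreener(d=d, n_mandatory=data.p0).fit(X, data.y)
    if not scr.converged_.any():
        raise ValueError("all features degenerate: no screening fit converged")
    return ScreeningResult(
        u=scr.u_,
        rank=scr.rank_,
        selected=scr.selected_,
        d=scr.d_,
        null_loglik=scr.null_loglik_,
        converged=scr.converged_,
        feature_names=data.feature_names,
    )
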