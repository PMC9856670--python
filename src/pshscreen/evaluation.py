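"""IPCW evaluation of predicted cumulative incidence.

Prediction accuracy for the cause-1 CIF is measured with the censoring-
weighted Brier score

    Err(t) = (1/n) sum_i (N_i(t) - F1_hat(t | X_i, Z_i))^2 W_i(t),

where N_i(t) indicates an observed cause-1 failure by t and the inverse
probability of censoring weights

    W_i(t) = I(Y_i <= t, cause_i != 0) / G(Y_i)  +  I(Y_i > t) / G(t)

restore the representativeness of subjects whose status at t is known
(G is the marginal Kaplan-Meier censoring survival Pr(C >= t), evaluated
left-continuously; subjects censored before t get weight zero).  The
optimism-corrected .632+ bootstrap blends the apparent error with the
out-of-bag bootstrap error, and time-dependent ROC/AUC at a fixed horizon
treats cause-1 failures by the horizon as cases and both survivors and
competing-event subjects (known cause-1-free) as controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .censoring import km_censoring
from .data import CompetingRisksDataset
from .stepfun import StepFunction

__all__ = [
    "PredictionErrorCurve",
    "RocResult",
    "ipcw_weights",
    "brier_cif",
    "dot632plus",
    "roc_cif",
]


@dataclass
class PredictionErrorCurve:
    times: np.ndarray
    err: np.ndarray
    model_label: str = ""
    estimator: str = "apparent"  # apparent | test | dot632plus
    ipcw_source: StepFunction = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "err": self.err,
                "model": self.model_label,
                "estimator": self.estimator,
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def mean(self) -> float:
        """Grid-averaged prediction error (integrated Brier up to scaling)."""
        return float(np.mean(self.err))


@dataclass
class RocResult:
    horizon: float
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# horizon={self.horizon}\tauc={self.auc:.6f}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def ipcw_weights(data: CompetingRisksDataset, times, G: StepFunction) -> np.ndarray:
    """W_i(t) matrix, shape (n, len(times))."""
    times = np.atleast_1d(np.asarray(times, float))
    G_at_Y = np.atleast_1d(G(data.time))
    G_at_t = np.atleast_1d(G(times))
    past_event = (data.time[:, None] <= times[None, :]) & (data.cause[:, None] != 0)
    still_in = data.time[:, None] > times[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        W = past_event / G_at_Y[:, None] + still_in / G_at_t[None, :]
    return np.nan_to_num(W, nan=0.0, posinf=0.0)


def brier_cif(
    data: CompetingRisksDataset,
    predictions: np.ndarray,
    G: StepFunction | None = None,
    times=None,
    model_label: str = "",
    estimator: str = "apparent",
) -> PredictionErrorCurve:
    """IPCW Brier curve for per-subject CIF predictions on a time grid.

    ``predictions``: array (n, len(times)) of F1_hat(t | X_i, Z_i).
    Grid points where the censoring survival has been exhausted
    (G(t) = 0) are truncated away with a warning.
    """
    if G is None:
        G = km_censoring(data)
    times = np.atleast_1d(np.asarray(times, float))
    predictions = np.asarray(predictions, float)
    if predictions.shape != (data.n, times.size):
        raise ValueError(f"predictions must have shape {(data.n, times.size)}")
    usable = np.atleast_1d(G(times)) > 0
    if not usable.all():
        warnings.warn("grid truncated where the censoring survival reaches 0")
    times, predictions = times[usable], predictions[:, usable]
    W = ipcw_weights(data, times, G)
    N = (data.time[:, None] <= times[None, :]) & (data.cause[:, None] == 1)
    err = np.mean((N.astype(float) - predictions) ** 2 * W, axis=0)
    return PredictionErrorCurve(times, err, model_label, estimator, G)


def dot632plus(
    data: CompetingRisksDataset,
    model_recipe,
    grid,
    B: int = 100,
    seed: int | None = None,
    model_label: str = "",
) -> PredictionErrorCurve:
    """Bootstrap .632+ prediction-error curve.

    ``model_recipe(train_data)`` must return a callable
    ``predict(eval_data, times) -> (n, len(times))`` of CIF predictions;
    it is refit on every bootstrap draw.  Out-of-bag subjects form each
    draw's test set, weighted by their own censoring curve; the final
    estimate blends the apparent error with the out-of-bag mean using the
    overfitting-relative weight of the .632+ rule.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap draws")
    grid = np.atleast_1d(np.asarray(grid, float))
    rng = np.random.default_rng(seed)

    predict_full = model_recipe(data)
    pred_app = np.asarray(predict_full(data, grid), float)
    G_full = km_censoring(data)
    err_app = brier_cif(data, pred_app, G_full, grid).err

    # no-information error: every subject's outcome scored against every
    # subject's prediction
    W = ipcw_weights(data, grid, G_full)
    N = ((data.time[:, None] <= grid[None, :]) & (data.cause[:, None] == 1)).astype(float)
    err_noinf = np.einsum("it,jt->t", N**2 * W, np.ones_like(pred_app)) / data.n**2
    err_noinf += np.einsum("it,jt->t", W, pred_app**2) / data.n**2
    err_noinf -= 2 * np.einsum("it,jt->t", N * W, pred_app) / data.n**2

    boot_sum = np.zeros_like(err_app)
    boot_count = np.zeros_like(err_app)
    for _ in range(B):
        idx = rng.integers(0, data.n, size=data.n)
        oob = np.setdiff1d(np.arange(data.n), idx)
        if oob.size < 2:
            continue
        boot_data = data.subset(idx)
        try:
            predict_b = model_recipe(boot_data)
        except ValueError:
            continue  # degenerate resample (e.g. no cause-1 events)
        oob_data = data.subset(oob)
        pred_oob = np.asarray(predict_b(oob_data, grid), float)
        G_oob = km_censoring(oob_data)
        usable = np.atleast_1d(G_oob(grid)) > 0
        err_b = np.full(grid.size, np.nan)
        err_b[usable] = brier_cif(oob_data, pred_oob[:, usable], G_oob, grid[usable]).err
        ok = np.isfinite(err_b)
        boot_sum[ok] += err_b[ok]
        boot_count[ok] += 1
    if not boot_count.all():
        raise ValueError("no usable out-of-bag draws at some grid points")
    err_boot = boot_sum / boot_count

    err = dot632plus_blend(err_app, err_boot, err_noinf)
    return PredictionErrorCurve(grid, err, model_label, "dot632plus", G_full)


def dot632plus_blend(err_app, err_boot, err_noinf) -> np.ndarray:
    """The .632+ blending rule, pointwise over the grid.

    Relative overfitting R = (err_boot - err_app)/(err_noinf - err_app)
    clamped to [0, 1] (and to 0 where the no-information error does not
    exceed the apparent error); weight w = .632/(1 - .368 R); the result
    is (1 - w) err_app + w err_boot.
    """
    err_app = np.asarray(err_app, float)
    err_boot = np.asarray(err_boot, float)
    err_noinf = np.asarray(err_noinf, float)
    denom = err_noinf - err_app
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (err_boot - err_app) / denom
    bad = denom <= 0
    if bad.any():
        warnings.warn("no-information error <= apparent error at some grid points; R set to 0")
    R = np.clip(np.where(bad, 0.0, R), 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    return (1.0 - w) * err_app + w * err_boot


def roc_cif(
    data: CompetingRisksDataset,
    marker,
    horizon: float,
    G: StepFunction | None = None,
) -> RocResult:
    """IPCW time-dependent ROC for a real-valued risk marker at a horizon.

    Cases: cause-1 failures by the horizon (weight 1/G(Y_i)).  Controls:
    subjects still event-free past the horizon (weight 1/G(horizon)) and
    competing-event failures by the horizon (weight 1/G(Y_i)); the latter
    are certain never to contribute a cause-1 event.  AUC is the weighted
    probability of concordance with ties counted 1/2.
    """
    if G is None:
        G = km_censoring(data)
    marker = np.asarray(marker, float)
    t = float(horizon)
    is_case = (data.time <= t) & (data.cause == 1)
    is_ctrl = (data.time > t) | ((data.time <= t) & (data.cause >= 2))
    if not is_case.any() or not is_ctrl.any():
        raise ValueError(f"no cases or no controls at horizon {t}")
    G_at_Y = np.atleast_1d(G(data.time))
    G_at_t = float(G(t))
    w = np.zeros(data.n)
    w[is_case] = 1.0 / G_at_Y[is_case]
    late = is_ctrl & (data.time > t)
    w[late] = 1.0 / G_at_t
    early_ctrl = is_ctrl & ~late
    w[early_ctrl] = 1.0 / G_at_Y[early_ctrl]

    mc, wc = marker[is_case], w[is_case]
    mk, wk = marker[is_ctrl], w[is_ctrl]
    thresholds = np.unique(marker)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in thresholds:
        tpr.append(wc[mc >= c].sum() / wc.sum())
        fpr.append(wk[mk >= c].sum() / wk.sum())
    tpr.append(1.0)
    fpr.append(1.0)

    # weighted concordance with ties at 1/2 (equals the trapezoidal area)
    order = np.argsort(mk, kind="stable")
    mk_s, wk_s = mk[order], wk[order]
    cum_w = np.concatenate([[0.0], np.cumsum(wk_s)])
    lo = np.searchsorted(mk_s, mc, side="left")
    hi = np.searchsorted(mk_s, mc, side="right")
    below = cum_w[lo]
    ties = cum_w[hi] - cum_w[lo]
    auc = float(np.sum(wc * (below + 0.5 * ties)) / (wc.sum() * wk.sum()))
    return RocResult(
        horizon=t,
        fpr=np.asarray(fpr),
        tpr=np.asarray(tpr),
        auc=auc,
        n_cases=int(is_case.sum()),
        n_controls=int(is_ctrl.sum()),
    )
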