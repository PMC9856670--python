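"""Piecewise-constant curves on the time axis.

Survival-analysis quantities in this package — the censoring survival
curve G(t) = Pr(C >= t), cumulative baseline subdistribution hazards,
cumulative incidence functions — are all step functions with jumps at
observed event times.  The only subtlety is the convention at a jump
point: a curve estimating Pr(C >= t) must be *left*-continuous (the drop
caused by a censoring at time t takes effect strictly after t), whereas
Nelson-Aalen/Breslow cumulative hazards and CIFs are conventionally
*right*-continuous.  ``StepFunction`` carries that convention explicitly
so callers never have to remember which side a drop lands on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """A right- or left-continuous step function on [0, inf).

    Parameters
    ----------
    jump_times : array-like
        Strictly increasing, non-negative jump locations.
    values : array-like
        Function value attained *after* each jump (same length).
    initial_value : float
        Value on the segment before the first jump.
    continuity : {"right", "left"}
        ``"right"``: f(jump_times[k]) == values[k] (cadlag; hazards, CIFs).
        ``"left"``: f(jump_times[k]) == value before the jump (survival of
        the form Pr(. >= t)).
    """

    jump_times: np.ndarray
    values: np.ndarray
    initial_value: float = 1.0
    continuity: str = "right"
    #: non-fatal issues recorded during construction (e.g. zero tail mass)
    warnings: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.jump_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("jump_times and values must be 1-D and equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("jump_times must be strictly increasing and >= 0")
        if self.continuity not in ("right", "left"):
            raise ValueError("continuity must be 'right' or 'left'")
        object.__setattr__(self, "jump_times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, times) -> np.ndarray:
        """Evaluate at ``times`` (scalar or array)."""
        times = np.asarray(times, dtype=float)
        side = "right" if self.continuity == "right" else "left"
        idx = np.searchsorted(self.jump_times, times, side=side)
        out = np.where(
            idx == 0,
            self.initial_value,
            self.values[np.clip(idx - 1, 0, max(len(self.values) - 1, 0))]
            if self.values.size
            else self.initial_value,
        )
        return out if out.ndim else float(out)

    def before(self, times) -> np.ndarray:
        """Left limit f(t-): the value strictly before ``times``."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.jump_times, times, side="left")
        out = np.where(
            idx == 0,
            self.initial_value,
            self.values[np.clip(idx - 1, 0, max(len(self.values) - 1, 0))]
            if self.values.size
            else self.initial_value,
        )
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        """Two-column (time, value) table; serialisable as TSV."""
        return pd.DataFrame({"time": self.jump_times, "value": self.values})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def constant(cls, value: float, continuity: str = "right") -> "StepFunction":
        return cls(np.empty(0), np.empty(0), initial_value=value, continuity=continuity)
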