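"""Competing-risks dataset container, delimited-text IO and cohort splitting.

A study ships as two delimited tables: a clinical table (one row per
subject: identifier, follow-up time, cause-of-failure code, control
covariates such as age or treatment) and a feature table (identifier plus
the high-dimensional measurements subject to screening, e.g. gene
expression).  Cause codes follow the usual competing-risks convention:
0 = censored, 1 = event of interest, 2.. = competing causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompetingRisksDataset",
    "SplitResult",
    "crisk_target",
    "read_dataset",
    "write_dataset",
    "split_train_test",
]

#: structured dtype used as the ``y`` of the scikit-learn style estimators
CRISK_DTYPE = np.dtype([("cause", np.int64), ("time", np.float64)])


def crisk_target(time, cause) -> np.ndarray:
    """Pack follow-up times and cause codes into a structured target array."""
    time = np.asarray(time, dtype=float)
    cause = np.asarray(cause, dtype=np.int64)
    if time.shape != cause.shape or time.ndim != 1:
        raise ValueError("time and cause must be 1-D with matching length")
    y = np.empty(time.shape[0], dtype=CRISK_DTYPE)
    y["time"] = time
    y["cause"] = cause
    return y


class ValidationError(ValueError):
    """Raised when an input table violates the dataset invariants."""


@dataclass
class CompetingRisksDataset:
    """Subjects with follow-up, cause code, screened features X and controls Z.

    Invariants (enforced by :meth:`validate`): finite non-negative times,
    integer cause codes >= 0, no missing values, unique feature/control
    names, at least two subjects.
    """

    subject_id: np.ndarray
    time: np.ndarray
    cause: np.ndarray
    X: pd.DataFrame
    Z: pd.DataFrame

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.time = np.asarray(self.time, dtype=float)
        self.cause = np.asarray(self.cause, dtype=np.int64)
        self.X = pd.DataFrame(self.X).reset_index(drop=True)
        self.Z = pd.DataFrame(self.Z).reset_index(drop=True)
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def p0(self) -> int:
        return self.Z.shape[1]

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)

    @property
    def control_names(self) -> list:
        return list(self.Z.columns)

    @property
    def y(self) -> np.ndarray:
        """Structured (cause, time) target for the estimator layer."""
        return crisk_target(self.time, self.cause)

    def validate(self) -> None:
        n = len(self.time)
        if n < 2:
            raise ValidationError("need at least 2 subjects")
        for name, arr in (("subject_id", self.subject_id), ("cause", self.cause)):
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != n={n}")
        bad = ~np.isfinite(self.time) | (self.time < 0)
        if bad.any():
            rows = np.flatnonzero(bad)
            raise ValidationError(
                f"non-finite or negative times in rows {rows.tolist()} "
                f"(subjects {self.subject_id[rows].tolist()})"
            )
        if (self.cause < 0).any():
            rows = np.flatnonzero(self.cause < 0)
            raise ValidationError(f"negative cause codes in rows {rows.tolist()}")
        for label, df in (("feature", self.X), ("control", self.Z)):
            if len(df) != n:
                raise ValidationError(f"{label} matrix has {len(df)} rows, expected {n}")
            if df.columns.duplicated().any():
                dup = df.columns[df.columns.duplicated()].tolist()
                raise ValidationError(f"duplicated {label} column names: {dup}")
            if df.shape[1] and not np.isfinite(df.to_numpy(dtype=float)).all():
                raise ValidationError(f"missing/non-finite values in {label} matrix")
        if len(np.unique(self.subject_id)) != n:
            raise ValidationError("subject identifiers are not unique")

    def subset(self, index) -> "CompetingRisksDataset":
        """Row subset by positional index, preserving order.

        Repeated indices (bootstrap resampling) get suffixed identifiers
        to keep subject labels unique.
        """
        index = np.asarray(index, dtype=int)
        ids = self.subject_id[index].astype(str)
        if len(np.unique(ids)) != len(ids):
            counts = {}
            out = []
            for s in ids:
                counts[s] = counts.get(s, 0) + 1
                out.append(s if counts[s] == 1 else f"{s}#{counts[s]}")
            ids = np.asarray(out)
        return CompetingRisksDataset(
            subject_id=ids,
            time=self.time[index],
            cause=self.cause[index],
            X=self.X.iloc[index],
            Z=self.Z.iloc[index],
        )

    # -- counting-process views -------------------------------------------
    def event_indicator(self, t: float) -> np.ndarray:
        """N_i(t) = 1 if subject i failed from cause 1 by time t."""
        return ((self.time <= t) & (self.cause == 1)).astype(float)

    def at_risk(self, t: float) -> np.ndarray:
        """Subdistribution risk indicator R_i(t) = 1 - N_i(t-).

        Subjects stay in the Fine-Gray risk set after censoring or a
        competing event; only a cause-1 failure strictly before t removes
        them.
        """
        return 1.0 - ((self.time < t) & (self.cause == 1)).astype(float)


@dataclass
class SplitResult:
    train_index: np.ndarray
    test_index: np.ndarray
    strata_report: pd.DataFrame = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# IO


def read_dataset(
    clinical_path,
    features_path,
    *,
    id_col: str = "id",
    time_col: str = "time",
    cause_col: str = "cause",
    control_cols=None,
    sep=None,
) -> CompetingRisksDataset:
    """Read and join the clinical and feature tables.

    Any clinical column other than id/time/cause is treated as a control
    covariate unless ``control_cols`` names them explicitly.  Categorical
    (non-numeric) controls are expanded to indicator columns with the
    first level (alphabetical) as reference.  Subjects must appear in both
    tables; output order follows the clinical table.
    """
    clin = pd.read_csv(clinical_path, sep=sep, engine="python")
    feat = pd.read_csv(features_path, sep=sep, engine="python")
    for col in (id_col, time_col, cause_col):
        if col not in clin.columns:
            raise ValidationError(f"clinical table lacks required column {col!r}")
    if control_cols is None:
        control_cols = [c for c in clin.columns if c not in (id_col, time_col, cause_col)]
    missing = [c for c in control_cols if c not in clin.columns]
    if missing:
        raise ValidationError(f"control columns not in clinical table: {missing}")

    fid = feat.columns[0]
    clin_ids = clin[id_col].astype(str)
    feat = feat.set_index(feat[fid].astype(str)).drop(columns=[fid])
    unmatched = sorted(set(clin_ids) - set(feat.index))
    if unmatched:
        raise ValidationError(f"subjects missing from feature table: {unmatched}")
    feat = feat.loc[clin_ids].reset_index(drop=True)

    time = pd.to_numeric(clin[time_col], errors="coerce")
    cause = pd.to_numeric(clin[cause_col], errors="coerce")
    for name, series in (("time", time), ("cause", cause)):
        if series.isna().any():
            rows = series.index[series.isna()].tolist()
            raise ValidationError(f"unparseable {name} values in clinical rows {rows}")

    Z = _encode_controls(clin[control_cols]) if control_cols else pd.DataFrame(index=clin.index)
    return CompetingRisksDataset(
        subject_id=clin_ids.to_numpy(),
        time=time.to_numpy(dtype=float),
        cause=cause.to_numpy(dtype=np.int64),
        X=feat,
        Z=Z,
    )


def _encode_controls(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric controls pass through; categoricals become reference-coded
    indicators (first sorted level dropped)."""
    cols = {}
    for c in df.columns:
        numeric = pd.to_numeric(df[c], errors="coerce")
        if numeric.notna().all():
            cols[c] = numeric.astype(float)
        else:
            levels = sorted(df[c].astype(str).unique())
            for lev in levels[1:]:
                cols[f"{c}_{lev}"] = (df[c].astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=df.index)


def write_dataset(data: CompetingRisksDataset, clinical_path, features_path, sep="\t") -> None:
    """Write the two-table representation read back by :func:`read_dataset`."""
    clin = pd.DataFrame({"id": data.subject_id, "time": data.time, "cause": data.cause})
    clin = pd.concat([clin, data.Z.reset_index(drop=True)], axis=1)
    clin.to_csv(clinical_path, sep=sep, index=False)
    feat = pd.concat(
        [pd.DataFrame({"id": data.subject_id}), data.X.reset_index(drop=True)], axis=1
    )
    feat.to_csv(features_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Splitting


def split_train_test(
    data: CompetingRisksDataset,
    ratio=(4, 1),
    seed: int = 0,
    *,
    n_bins: int = 4,
    allow_all_train: bool = False,
) -> SplitResult:
    """Stratified random train/test split.

    Strata are the cross of the cause code with quantile bins of the first
    control column, so both cohorts share similar event composition and
    clinical profile.  Per stratum the train share matches
    ratio[0]/(ratio[0]+ratio[1]) to within one subject.
    """
    tr, te = int(ratio[0]), int(ratio[1])
    if tr < 1 or te < 0 or (te == 0 and not allow_all_train):
        raise ValueError(f"degenerate split ratio {ratio!r}")
    frac = tr / (tr + te)
    rng = np.random.default_rng(seed)

    strata = data.cause.astype(str)
    if data.p0 > 0:
        z0 = data.Z.iloc[:, 0].to_numpy(dtype=float)
        if np.unique(z0).size > n_bins:
            bins = pd.qcut(z0, q=n_bins, labels=False, duplicates="drop")
        else:
            bins = pd.factorize(z0)[0]
        strata = np.char.add(np.char.add(strata, ":"), np.asarray(bins).astype(str))

    # largest-remainder apportionment: every stratum gets floor or ceil of
    # frac*|s| train slots and the overall train size is round(frac*n)
    labels = np.unique(strata)
    sizes = np.array([np.sum(strata == s) for s in labels])
    quota = frac * sizes
    n_train = np.floor(quota).astype(int)
    n_extra = int(round(frac * data.n)) - int(n_train.sum())
    if n_extra > 0:
        order = np.lexsort((rng.random(len(labels)), -(quota - n_train)))
        n_train[order[:n_extra]] += 1

    train_idx, test_idx, report = [], [], []
    for s, members_n, n_tr in zip(labels, sizes, n_train):
        members = np.flatnonzero(strata == s)
        perm = rng.permutation(members)
        train_idx.append(perm[:n_tr])
        test_idx.append(perm[n_tr:])
        report.append({"stratum": s, "n": int(members_n), "train": int(n_tr), "test": int(members_n - n_tr)})

    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx)) if any(len(t) for t in test_idx) else np.empty(0, int)
    return SplitResult(train, test, pd.DataFrame(report))
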