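"""The five normalization operators applied to the beat matrix.

The dataset is a matrix ``A`` of m beats (rows) by n sample positions
(columns).  Four classical operators work column-wise — per sample
position across beats — and therefore cannot remove per-beat amplitude
offsets and gains, which is exactly how heterogeneous databases differ.
The fifth, *self-processing*, z-scores each beat against its own mean
and sample standard deviation (row-wise), making the result invariant
to any per-beat affine amplitude change while preserving morphology.

Column statistics can be fit on a training split and applied unchanged
to a test split (the default, leakage-free path) or computed pooled.
All standard deviations are sample standard deviations (ddof = 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateColumnError, FlatlineBeatError

logger = logging.getLogger(__name__)

_STD_TOL = 1e-12


@dataclass
class BeatDataset:
    """m beats x n samples with integer class labels and per-beat provenance."""

    A: np.ndarray
    labels: np.ndarray
    provenance: pd.DataFrame = None  # columns: source_db, source_record

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.A.ndim != 2:
            raise ValueError("A must be 2-D (beats x samples)")
        if len(self.labels) != self.A.shape[0]:
            raise ValueError("labels length must equal number of beats")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("beat matrix contains non-finite values")
        if self.provenance is None:
            self.provenance = pd.DataFrame(
                {"source_db": [""] * len(self), "source_record": [""] * len(self)}
            )
        self.provenance = self.provenance.reset_index(drop=True)
        if len(self.provenance) != len(self):
            raise ValueError("provenance length must equal number of beats")

    def __len__(self) -> int:
        return self.A.shape[0]

    @property
    def n_samples_per_beat(self) -> int:
        return self.A.shape[1]

    def subset(self, idx) -> "BeatDataset":
        idx = np.asarray(idx)
        return BeatDataset(
            self.A[idx], self.labels[idx], self.provenance.iloc[idx]
        )

    @classmethod
    def from_heartbeats(cls, beats) -> "BeatDataset":
        if not beats:
            raise ValueError("no beats")
        return cls(
            A=np.stack([b.samples for b in beats]),
            labels=np.array([b.label for b in beats]),
            provenance=pd.DataFrame(
                {
                    "source_db": [b.source_db for b in beats],
                    "source_record": [b.source_record for b in beats],
                }
            ),
        )


# ---------------------------------------------------------------------------
# the five operators (array level)
# ---------------------------------------------------------------------------


def standardize_columns(A: np.ndarray) -> np.ndarray:
    """Column-wise z-score: subtract the column mean, divide by its
    sample standard deviation."""
    A = _check_matrix(A, min_rows=2)
    mu = A.mean(axis=0)
    sd = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= _STD_TOL)
    if bad.size:
        raise DegenerateColumnError(bad, what="zero-variance")
    return (A - mu) / sd


def extremum_scale(A: np.ndarray) -> np.ndarray:
    """Min-max scaling per column into [0, 1]; constant columns map to 0."""
    A = _check_matrix(A, min_rows=2)
    lo, hi = A.min(axis=0), A.max(axis=0)
    span = hi - lo
    flat = span <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant column(s) mapped to 0 by extremum_scale",
            stacklevel=2,
        )
        span = np.where(flat, 1.0, span)
    out = (A - lo) / span
    out[:, flat] = 0.0
    return out


def mean_scale(A: np.ndarray) -> np.ndarray:
    """Divide each column by its mean (keeps relative spread information)."""
    A = _check_matrix(A, min_rows=1)
    mu = A.mean(axis=0)
    bad = np.flatnonzero(np.abs(mu) <= _STD_TOL)
    if bad.size:
        raise DegenerateColumnError(bad, what="zero-mean")
    return A / mu


def std_scale(A: np.ndarray) -> np.ndarray:
    """Divide each column by its sample standard deviation (mean kept)."""
    A = _check_matrix(A, min_rows=2)
    sd = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= _STD_TOL)
    if bad.size:
        raise DegenerateColumnError(bad, what="zero-variance")
    return A / sd


def self_process(A: np.ndarray) -> np.ndarray:
    """Per-beat z-score: each row minus its own mean, over its own
    sample standard deviation.

    Invariant to per-beat affine amplitude changes (gain and offset) and
    idempotent.  Flatline beats
    (zero row std) raise; dataset-level callers drop and log them
    instead (see :func:`preprocess_dataset`).
    """
    A = _check_matrix(A, min_rows=1)
    if A.shape[1] < 2:
        raise ValueError("beats must have at least 2 samples")
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() <= _STD_TOL)
    if flat.size:
        raise FlatlineBeatError(flat)
    return (A - mu) / sd


def flatline_rows(A: np.ndarray) -> np.ndarray:
    """Row indices whose sample standard deviation is (numerically) zero."""
    A = np.asarray(A, dtype=np.float64)
    return np.flatnonzero(A.std(axis=1, ddof=1) <= _STD_TOL)


def _check_matrix(A, min_rows: int) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError("expected a 2-D beat matrix")
    if A.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} beats, got {A.shape[0]}")
    return A


OPERATORS: dict[str, Optional[Callable[[np.ndarray], np.ndarray]]] = {
    "none": None,
    "standardize": standardize_columns,
    "extremum": extremum_scale,
    "mean": mean_scale,
    "std": std_scale,
    "self": self_process,
}

COLUMN_WISE = {"standardize", "extremum", "mean", "std"}


# ---------------------------------------------------------------------------
# train/test-aware column statistics
# ---------------------------------------------------------------------------


@dataclass
class ColumnStats:
    """Column statistics of a training matrix, reusable on a test matrix.

    Avoids test-set leakage for the four column-wise operators; the
    row-wise self-processing operator needs no shared statistics.
    """

    method: str
    mean: np.ndarray = field(default=None, repr=False)  # type: ignore
    std: np.ndarray = field(default=None, repr=False)  # type: ignore
    min: np.ndarray = field(default=None, repr=False)  # type: ignore
    max: np.ndarray = field(default=None, repr=False)  # type: ignore

    @classmethod
    def fit(cls, A: np.ndarray, method: str) -> "ColumnStats":
        if method not in COLUMN_WISE:
            raise ValueError(f"{method!r} is not a column-wise operator")
        A = _check_matrix(A, min_rows=2)
        return cls(
            method=method,
            mean=A.mean(axis=0),
            std=A.std(axis=0, ddof=1),
            min=A.min(axis=0),
            max=A.max(axis=0),
        )

    def transform(self, A: np.ndarray) -> np.ndarray:
        A = _check_matrix(A, min_rows=1)
        if self.method == "standardize":
            bad = np.flatnonzero(self.std <= _STD_TOL)
            if bad.size:
                raise DegenerateColumnError(bad, what="zero-variance")
            return (A - self.mean) / self.std
        if self.method == "std":
            bad = np.flatnonzero(self.std <= _STD_TOL)
            if bad.size:
                raise DegenerateColumnError(bad, what="zero-variance")
            return A / self.std
        if self.method == "mean":
            bad = np.flatnonzero(np.abs(self.mean) <= _STD_TOL)
            if bad.size:
                raise DegenerateColumnError(bad, what="zero-mean")
            return A / self.mean
        # extremum
        span = self.max - self.min
        flat = span <= 0
        span = np.where(flat, 1.0, span)
        out = (A - self.min) / span
        out[:, flat] = 0.0
        return out


def preprocess_dataset(
    dataset: BeatDataset,
    method: str,
    stats: Optional[ColumnStats] = None,
) -> tuple[BeatDataset, pd.DataFrame]:
    """Apply a named operator to a dataset.

    Returns the transformed dataset and a drop log (non-empty only for
    ``"self"`` when flatline beats had to be rejected — one flat beat
    must not abort a database build).  For column-wise methods pass a
    fitted :class:`ColumnStats` to reuse training statistics; with
    ``stats=None`` statistics come from ``dataset`` itself (pooled).
    """
    if method not in OPERATORS:
        raise ValueError(f"unknown preprocessing method {method!r}; "
                         f"choose from {sorted(OPERATORS)}")
    empty_log = pd.DataFrame(columns=["source_db", "source_record", "row", "reason"])
    if method == "none":
        return dataset, empty_log
    if method == "self":
        flat = flatline_rows(dataset.A)
        if flat.size:
            log = dataset.provenance.iloc[flat][["source_db", "source_record"]].copy()
            log["row"] = flat
            log["reason"] = "flatline_beat"
            logger.warning("self_process dropped %d flatline beat(s)", flat.size)
            keep = np.setdiff1d(np.arange(len(dataset)), flat)
            dataset = dataset.subset(keep)
        else:
            log = empty_log
        out = dataset.A if len(dataset) == 0 else self_process(dataset.A)
        return BeatDataset(out, dataset.labels, dataset.provenance), log
    if stats is None:
        stats = ColumnStats.fit(dataset.A, method)
    return (
        BeatDataset(stats.transform(dataset.A), dataset.labels, dataset.provenance),
        empty_log,
    )
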