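"""Per-beat windowing, beat extraction around annotated R peaks, and
sampling-frequency unification.

The window length comes from heart-rate physiology: a resting heart
beats 60–100 times per minute, so at sampling frequency ``f_sample`` a
single beat spans between ``0.6 * f_sample`` and ``f_sample`` samples.
Beats are cut as M samples before the R peak and N after it (M + N + 1
= L), and records at a foreign sampling frequency are unified by
band-limited polyphase resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

import numpy as np
from scipy.signal import resample_poly

from .errors import DomainError
from .record_io import BeatAnnotationSet, EcgRecord

HEART_RATE_MIN = 60.0  # bpm, resting lower bound
HEART_RATE_MAX = 100.0  # bpm, above which is tachycardia


def num_of_sample(f_heart: float, f_sample: float) -> int:
    """Samples spanned by one beat at heart rate ``f_heart`` (bpm).

    ``round(60 * f_sample / f_heart)``; within the resting heart-rate
    band the result lies in ``[0.6 * f_sample, f_sample]``.
    """
    if not (HEART_RATE_MIN <= f_heart <= HEART_RATE_MAX):
        raise DomainError(
            f"f_heart={f_heart} outside resting band "
            f"[{HEART_RATE_MIN:g}, {HEART_RATE_MAX:g}] bpm"
        )
    if f_sample <= 0:
        raise DomainError(f"f_sample must be positive, got {f_sample}")
    return int(round(60.0 * f_sample / f_heart))


def split_window(L: int) -> tuple[int, int]:
    """Split a beat of L samples into (M before R, N after R), M + N + 1 = L."""
    if L < 3:
        raise DomainError(f"window length must be >= 3, got {L}")
    M = (L - 1) // 2
    return M, L - 1 - M


@dataclass(frozen=True)
class WindowSpec:
    """Samples per beat and its split around the R peak, at the target fs."""

    L: int = 260
    fs_target: float = 360.0
    M: int = field(default=None)  # type: ignore[assignment]
    N: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        M, N = self.M, self.N
        if M is None or N is None:
            M, N = split_window(self.L)
            object.__setattr__(self, "M", M)
            object.__setattr__(self, "N", N)
        if self.M + self.N + 1 != self.L or self.M < 0 or self.N < 0:
            raise DomainError(f"invalid window split M={self.M} N={self.N} L={self.L}")
        if self.fs_target <= 0:
            raise DomainError("fs_target must be positive")
        if not (0.6 * self.fs_target <= self.L <= self.fs_target):
            raise DomainError(
                f"L={self.L} outside the physiological band "
                f"[{0.6 * self.fs_target:g}, {self.fs_target:g}] at "
                f"fs_target={self.fs_target:g}"
            )

    def at_native_fs(self, fs_native: float) -> tuple[int, int, int]:
        """Window (L, M, N) rescaled to a record's native sampling rate."""
        if fs_native == self.fs_target:
            return self.L, self.M, self.N
        L_nat = int(round(self.L * fs_native / self.fs_target))
        L_nat = max(L_nat, 3)
        M_nat, N_nat = split_window(L_nat)
        return L_nat, M_nat, N_nat


@dataclass
class Heartbeat:
    """One fixed-length beat with its class label and provenance."""

    samples: np.ndarray
    label: int
    source_record: str = ""
    source_db: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()


@dataclass
class DropLogEntry:
    record_id: str
    r_index: int
    reason: str


def resample(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Band-limited resampling from fs_in to fs_out.

    Output length is ``round(len * fs_out / fs_in)``.  DC and all
    content below min(fs_in, fs_out)/2 are preserved; fs_out == fs_in
    is the identity.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if x.size == 0:
        raise DomainError("cannot resample an empty signal")
    if fs_in <= 0 or fs_out <= 0:
        raise DomainError("sampling frequencies must be positive")
    if fs_in == fs_out:
        return x.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    # remove/restore the mean so DC passes exactly (the anti-aliasing
    # FIR has finite passband ripple) and edge transients shrink
    mx = x.mean()
    y = resample_poly(x - mx, up, down, padtype="line") + mx
    target = int(round(len(x) * fs_out / fs_in))
    if len(y) > target:
        y = y[:target]
    elif len(y) < target:
        y = np.concatenate([y, np.repeat(y[-1], target - len(y))])
    return y


def _resample_to_length(beat: np.ndarray, fs_in: float, fs_out: float, L: int) -> np.ndarray:
    """Resample a beat and force exactly L samples (±1 edge fix-up)."""
    y = resample(beat, fs_in, fs_out)
    if len(y) > L:
        y = y[:L]
    elif len(y) < L:
        y = np.concatenate([y, np.repeat(y[-1], L - len(y))])
    return y


def extract_beats(
    record: EcgRecord,
    annotations: BeatAnnotationSet,
    window: WindowSpec,
    class_map,
) -> tuple[list[Heartbeat], list[DropLogEntry]]:
    """Cut one fixed-length beat around every mappable R-peak annotation.

    Extraction happens at the record's native sampling rate with the
    window rescaled accordingly; beats from foreign-rate records are
    then resampled to exactly ``window.L`` samples at
    ``window.fs_target``.  Windows that cross a record boundary are
    dropped and logged; annotation symbols the class map does not know
    are skipped silently (rhythm marks, artifacts, excluded classes).
    """
    if record.n_leads != 1:
        raise DomainError(
            f"extract_beats needs a single-lead record, got {record.n_leads} leads"
        )
    x = record.signal[:, 0]
    n = len(x)
    L_nat, M_nat, N_nat = window.at_native_fs(record.fs)
    needs_resample = record.fs != window.fs_target

    beats: list[Heartbeat] = []
    dropped: list[DropLogEntry] = []
    for r, sym in zip(annotations.r_indices, annotations.symbols):
        label = class_map.label_for(sym)
        if label is None:
            continue
        r = int(r)
        lo, hi = r - M_nat, r + N_nat
        if lo < 0:
            dropped.append(DropLogEntry(record.record_id, r, "boundary_underflow"))
            continue
        if hi >= n:
            dropped.append(DropLogEntry(record.record_id, r, "boundary_overflow"))
            continue
        seg = x[lo : hi + 1]
        if needs_resample:
            seg = _resample_to_length(seg, record.fs, window.fs_target, window.L)
        beats.append(
            Heartbeat(
                samples=seg,
                label=label,
                source_record=record.record_id,
                source_db=record.source_db,
            )
        )
    return beats, dropped


def write_drop_log(entries: Iterable[DropLogEntry], path) -> None:
    """Persist a drop log as CSV (record_id, r_index, reason)."""
    import pandas as pd

    pd.DataFrame(
        [(e.record_id, e.r_index, e.reason) for e in entries],
        columns=["record_id", "r_index", "reason"],
    ).to_csv(path, index=False)
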