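"""Seeded synthetic multi-database ECG corpora.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T waves) drawn
from a per-class morphology template, placed at R-R intervals sampled
from a resting heart-rate range.  A database profile adds the three
classical ECG noise processes — baseline wander (a 0.2–0.5 Hz drift),
powerline interference (a 50 Hz sinusoid) and electromyographic noise
(white noise band-limited to 5 Hz–Nyquist) — and an affine amplitude
distortion (gain and offset) emulating device/population differences
between source databases.  Annotations sit exactly at the R-bump
extremum, so every pipeline stage downstream is testable against
planted ground truth.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt

from .errors import DomainError, RecordIOError
from .integration import ClassMap, build_class_map
from .record_io import BeatAnnotationSet, EcgRecord, write_record

_WAVES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class MorphologySpec:
    """Five Gaussian bumps (amp mV, center s relative to R, sigma s)."""

    amps: tuple[float, ...]
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    amp_jitter: float = 0.05
    width_jitter: float = 0.05
    time_jitter: float = 0.004

    def __post_init__(self):
        if not (len(self.amps) == len(self.centers) == len(self.widths) == 5):
            raise DomainError("a morphology needs exactly 5 waves (P,Q,R,S,T)")
        if any(w <= 0 for w in self.widths):
            raise DomainError("wave widths must be positive")
        if abs(self.amps[2]) < max(abs(a) for a in self.amps):
            raise DomainError("the R bump must dominate in magnitude")


def load_morphologies(path=None) -> dict[int, MorphologySpec]:
    """Class-id → morphology table from the bundled (or a user) YAML file."""
    if path is not None:
        text = Path(path).read_text()
    else:
        text = (resources.files("ecgfuse") / "data" / "morphologies.yaml").read_text()
    doc = yaml.safe_load(text)
    jit = doc.get("default_jitter", {})
    out = {}
    for cid, waves in doc["classes"].items():
        out[int(cid)] = MorphologySpec(
            amps=tuple(waves[w]["amp"] for w in _WAVES),
            centers=tuple(waves[w]["center"] for w in _WAVES),
            widths=tuple(waves[w]["width"] for w in _WAVES),
            amp_jitter=jit.get("amp", 0.05),
            width_jitter=jit.get("width", 0.05),
            time_jitter=jit.get("time", 0.004),
        )
    return out


@dataclass
class DatabaseProfile:
    """How one source database records the same physiology.

    ``gain``/``offset`` apply an affine amplitude distortion to the
    whole record (device scale + baseline level); noise levels are
    standard-deviation-like amplitudes in mV *before* the gain.
    ``beat_gain_sigma`` and ``beat_offset_mv`` add per-beat amplitude
    scale (lognormal) and local baseline shift fluctuations — the
    within-database amplitude spread that per-beat normalization is
    designed to remove.
    """

    name: str
    fs: float = 360.0
    lead: str = "MLII"
    gain: float = 1.0
    offset: float = 0.0
    beat_gain_sigma: float = 0.15
    beat_offset_mv: float = 0.1
    baseline_wander_mv: float = 0.05
    baseline_wander_hz: tuple[float, float] = (0.2, 0.5)
    powerline_mv: float = 0.02
    powerline_hz: float = 50.0
    emg_mv: float = 0.02
    heart_rate_bpm: tuple[float, float] = (60.0, 100.0)
    mixture: dict[int, float] = field(default_factory=dict)
    margin_s: float = 1.0

    def __post_init__(self):
        if self.fs <= 0:
            raise DomainError("fs must be positive")
        if not self.mixture:
            self.mixture = {cid: 1.0 / 8 for cid in (0, 3, 6, 7, 9, 12, 13, 14)}
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"class mixture must sum to 1, got {total}")


def default_profiles(noise_scale: float = 1.0,
                     mixture: Optional[dict[int, float]] = None
                     ) -> list[DatabaseProfile]:
    """Three profiles emulating the heterogeneity of real arrhythmia
    databases: 360/128/257 Hz with distinct amplitude scales/offsets."""
    common = dict(
        baseline_wander_mv=0.05 * noise_scale,
        powerline_mv=0.02 * noise_scale,
        emg_mv=0.02 * noise_scale,
        mixture=dict(mixture) if mixture else {},
    )
    return [
        DatabaseProfile(name="db360", fs=360.0, lead="MLII",
                        gain=1.0, offset=0.0, **common),
        DatabaseProfile(name="db128", fs=128.0, lead="ECG1",
                        gain=0.55, offset=0.15, **common),
        DatabaseProfile(name="db257", fs=257.0, lead="V4",
                        gain=3.5, offset=-1.0,
                        beat_gain_sigma=0.45, beat_offset_mv=0.3, **common),
    ]


def generate_record(
    profile: DatabaseProfile,
    n_beats: int,
    seed: int,
    morphologies: Optional[dict[int, MorphologySpec]] = None,
    class_map: Optional[ClassMap] = None,
    record_id: str = "rec000",
) -> tuple[EcgRecord, BeatAnnotationSet, np.ndarray]:
    """One annotated single-lead record with ``n_beats`` planted beats.

    R-R intervals are drawn per beat from the profile's heart-rate
    range; the annotation index is the sample at each beat's R-bump
    center.  Returns (record, annotations, true class labels).
    """
    if n_beats < 1:
        raise DomainError("n_beats must be >= 1")
    if morphologies is None:
        morphologies = load_morphologies()
    if class_map is None:
        class_map = build_class_map()
    id_to_code = {cid: code for code, cid in class_map.code_to_id.items()}
    rng = np.random.default_rng(seed)

    cids = np.array(sorted(profile.mixture))
    probs = np.array([profile.mixture[c] for c in cids])
    labels = rng.choice(cids, size=n_beats, p=probs)

    fs = profile.fs
    hr = rng.uniform(*profile.heart_rate_bpm, size=n_beats)
    rr = 60.0 / hr * fs  # samples per beat interval
    r_pos = profile.margin_s * fs + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    r_idx = np.round(r_pos).astype(np.int64)
    n = int(r_idx[-1] + round(profile.margin_s * fs)) + 1

    t = np.arange(n) / fs
    clean = np.zeros(n)
    for k, (r, cid) in enumerate(zip(r_idx, labels)):
        m = morphologies[int(cid)]
        t_r = r / fs
        beat_scale = float(np.exp(profile.beat_gain_sigma * rng.standard_normal()))
        if profile.beat_offset_mv > 0:
            # local baseline shift: a broad pedestal under this beat
            # slow enough (sigma 1.2 s) to be near-constant across one
            # beat window, so it acts as a per-beat affine offset
            ped = profile.beat_offset_mv * rng.standard_normal()
            lo = max(0, int((t_r - 4.0) * fs))
            hi = min(n, int((t_r + 4.0) * fs) + 1)
            clean[lo:hi] += ped * np.exp(-0.5 * ((t[lo:hi] - t_r) / 1.2) ** 2)
        for w in range(5):
            amp = m.amps[w]
            if amp == 0.0:
                continue
            amp = beat_scale * amp * (1.0 + m.amp_jitter * rng.standard_normal())
            width = m.widths[w] * max(0.2, 1.0 + m.width_jitter * rng.standard_normal())
            center = t_r + m.centers[w]
            if w != 2:  # the R bump stays pinned to the annotation sample
                center += m.time_jitter * rng.standard_normal()
            lo = max(0, int((center - 5 * width) * fs))
            hi = min(n, int((center + 5 * width) * fs) + 1)
            if lo >= hi:
                continue
            clean[lo:hi] += amp * np.exp(
                -0.5 * ((t[lo:hi] - center) / width) ** 2
            )

    noise = np.zeros(n)
    if profile.baseline_wander_mv > 0:
        f_b = rng.uniform(*profile.baseline_wander_hz)
        noise += profile.baseline_wander_mv * np.sin(
            2 * np.pi * f_b * t + rng.uniform(0, 2 * np.pi)
        )
    if profile.powerline_mv > 0:
        noise += profile.powerline_mv * np.sin(
            2 * np.pi * profile.powerline_hz * t + rng.uniform(0, 2 * np.pi)
        )
    if profile.emg_mv > 0 and n > 30:
        white = rng.standard_normal(n)
        nyq = fs / 2.0
        sos = butter(4, [5.0 / nyq, min(0.95, (nyq - 1e-9) / nyq)], btype="band",
                     output="sos")
        emg = sosfiltfilt(sos, white)
        emg_std = emg.std()
        if emg_std > 0:
            noise += profile.emg_mv * emg / emg_std

    signal = profile.gain * (clean + noise) + profile.offset
    record = EcgRecord(
        record_id=record_id,
        signal=signal[:, None],
        fs=fs,
        lead_names=[profile.lead],
        source_db=profile.name,
        provenance={"synthetic": True, "seed": int(seed)},
    )
    symbols = [id_to_code[int(c)] for c in labels]
    ann = BeatAnnotationSet(r_idx, symbols)
    return record, ann, labels


def generate_corpus(
    profiles: Sequence[DatabaseProfile],
    n_records: int,
    seed: int,
    out_dir,
    n_beats_per_record: int = 100,
    dialect: str = "text",
    morphologies: Optional[dict[int, MorphologySpec]] = None,
    class_map: Optional[ClassMap] = None,
) -> dict:
    """Write an on-disk corpus: one directory per database profile.

    Each record gets signal + annotation files in the requested
    record_io dialect plus a ``<rec>.labels.csv`` ground-truth file;
    a ``manifest.json`` at the root lists everything.  Per-record seeds
    are derived from ``seed`` so corpora are reproducible.
    """
    if not profiles:
        raise DomainError("need at least one profile")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RecordIOError(f"cannot create corpus directory {out}: {exc}") from exc
    manifest = {"seed": int(seed), "n_records": int(n_records), "databases": []}
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(max(1, len(profiles) * n_records)))
    for profile in profiles:
        db_dir = out / profile.name
        db_dir.mkdir(exist_ok=True)
        entry = {"name": profile.name, "fs": profile.fs, "records": []}
        for i in range(n_records):
            rid = f"rec{i:03d}"
            rec_seed = int(next(child_seeds)) % (2**31)
            rec, ann, labels = generate_record(
                profile, n_beats_per_record, rec_seed,
                morphologies=morphologies, class_map=class_map, record_id=rid,
            )
            base = db_dir / rid
            write_record(rec, ann, base, dialect=dialect)
            rows = ["r_index,label"] + [
                f"{int(r)},{int(l)}" for r, l in zip(ann.r_indices, labels)
            ]
            (db_dir / f"{rid}.labels.csv").write_text("\n".join(rows) + "\n")
            entry["records"].append(rid)
        manifest["databases"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def zero_noise(profile: DatabaseProfile) -> DatabaseProfile:
    """Copy of a profile with every stochastic distortion switched off:
    the three noise processes and the per-beat amplitude fluctuation.
    Beats are then separable by construction (morphology jitter only),
    which makes this the sanity-oracle configuration for the pipeline."""
    return replace(profile, baseline_wander_mv=0.0, powerline_mv=0.0,
                   emg_mv=0.0, beat_gain_sigma=0.0, beat_offset_mv=0.0)
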