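"""Reading and writing ECG records and beat annotations.

Two on-disk dialects are supported:

* the PhysioNet WFDB convention — text header (``.hea``), format-212
  packed 12-bit signal (``.dat``) and the MIT annotation stream
  (``.atr``) — so real arrhythmia databases can be consumed directly;
* a documented plain-text fallback (``<rec>.sig.csv`` +
  ``<rec>.ann.csv`` + ``<rec>.meta.json``) so fixtures and synthetic
  corpora need no binary files at all.

Amplitudes are held in physical units (mV) in memory; the ADC gain
declared in the header bounds the write→read round-trip error to one
quantization step (1/gain mV).
"""

from __future__ import annotations

import json
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, RecordIOError

DEFAULT_GAIN = 200.0  # ADC units per mV, the MIT-BIH convention

# MIT annotation type codes (the WFDB ECGCODES table), restricted to the
# codes this pipeline can meet.  Beat codes carry a single-character
# mnemonic; non-beat codes (rhythm, noise, artifact) are preserved by the
# reader and filtered downstream by the class map.
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    22: '"', 25: "B", 26: "f", 28: "+", 30: "?", 31: "!", 34: "e",
    35: "n", 37: "x", 38: "P", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class EcgRecord:
    """A multi-lead sampled ECG signal in physical units (mV).

    ``signal`` is shaped (n_samples, n_leads); ``fs`` is the sampling
    frequency in Hz; ``provenance`` records which lead was selected and
    where the record came from.
    """

    record_id: str
    signal: np.ndarray
    fs: float
    lead_names: list[str]
    source_db: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.signal.shape[0] == 1 and self.signal.shape[1] > len(self.lead_names):
            self.signal = self.signal.T
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.signal.shape[1] != len(self.lead_names):
            raise ValueError(
                f"{self.signal.shape[1]} signal columns vs "
                f"{len(self.lead_names)} lead names"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite amplitudes")

    def __len__(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    def select_lead(self, lead_priority: Sequence[str]) -> "EcgRecord":
        """Return a single-lead view chosen by priority order.

        The first name in ``lead_priority`` present in this record wins;
        if none match, lead 0 is the documented fallback.
        """
        chosen = 0
        for name in lead_priority:
            if name in self.lead_names:
                chosen = self.lead_names.index(name)
                break
        prov = dict(self.provenance)
        prov["selected_lead"] = self.lead_names[chosen]
        return EcgRecord(
            record_id=self.record_id,
            signal=self.signal[:, [chosen]],
            fs=self.fs,
            lead_names=[self.lead_names[chosen]],
            source_db=self.source_db,
            provenance=prov,
        )


@dataclass
class BeatAnnotationSet:
    """R-peak sample indices (0-based) paired with single-character codes."""

    r_indices: np.ndarray
    symbols: list[str]

    def __post_init__(self):
        self.r_indices = np.asarray(self.r_indices, dtype=np.int64)
        if len(self.r_indices) != len(self.symbols):
            raise ValueError("r_indices and symbols length mismatch")
        if len(self.r_indices) > 1 and np.any(np.diff(self.r_indices) <= 0):
            raise ValueError("r_indices must be strictly increasing")
        if len(self.r_indices) and self.r_indices[0] < 0:
            raise ValueError("negative annotation index")

    def __len__(self) -> int:
        return len(self.r_indices)


# ---------------------------------------------------------------------------
# WFDB dialect
# ---------------------------------------------------------------------------

_HEA_SIGNAL_RE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\s+"
    r"(?P<gain>[-\d.]+)(?:\((?P<baseline>[-\d]+)\))?(?:/(?P<units>\S+))?"
    r"(?:\s+(?P<rest>.*))?$"
)


def _read_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(f"malformed header line in {hea_path}: {lines[0]!r}")
    name, n_sig = head[0], int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        m = _HEA_SIGNAL_RE.match(ln)
        if m is None:
            raise FormatError(f"unparseable signal line in {hea_path}: {ln!r}")
        gain = float(m.group("gain")) or DEFAULT_GAIN
        baseline = int(m.group("baseline") or 0)
        rest = (m.group("rest") or "").split()
        desc = rest[-1] if rest else f"lead{len(sigs)}"
        sigs.append(
            dict(
                file=m.group("file"),
                fmt=int(m.group("fmt")),
                gain=gain,
                baseline=baseline,
                desc=desc,
            )
        )
    if len(sigs) != n_sig:
        raise FormatError(f"header {hea_path} declares {n_sig} signals, found {len(sigs)}")
    return name, fs, n_samples, sigs


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    """Decode format-212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[: n_pairs * 3].reshape(-1, 3).astype(np.int32)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(n_pairs * 2, dtype=np.int32)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096
    if len(out) < n_values:
        raise FormatError(
            f"signal file truncated: {len(out)} values, expected {n_values}"
        )
    return out[:n_values]


def _pack_212(values: np.ndarray) -> bytes:
    v = np.asarray(values, dtype=np.int32).copy()
    if np.any((v < -2048) | (v > 2047)):
        v = np.clip(v, -2048, 2047)
    if len(v) % 2:
        v = np.concatenate([v, [0]])
    v = np.where(v < 0, v + 4096, v).astype(np.uint16).reshape(-1, 2)
    out = np.empty((len(v), 3), dtype=np.uint8)
    out[:, 0] = v[:, 0] & 0xFF
    out[:, 1] = ((v[:, 0] >> 8) & 0x0F) | (((v[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = v[:, 1] & 0xFF
    return out.tobytes()


def _read_atr(path: Path) -> BeatAnnotationSet:
    raw = path.read_bytes()
    indices, symbols = [], []
    t = 0
    pos = 0
    n = len(raw) - len(raw) % 2
    while pos < n:
        word = struct.unpack_from("<H", raw, pos)[0]
        pos += 2
        code, data = word >> 10, word & 0x3FF
        if code == 0 and data == 0:  # EOF
            break
        if code == _SKIP:
            if pos + 4 > len(raw):
                raise FormatError(f"truncated SKIP at byte {pos} in {path}")
            hi, lo = struct.unpack_from("<HH", raw, pos)
            pos += 4
            t += (hi << 16) | lo
        elif code == _AUX:
            pos += data + (data & 1)  # aux string, padded to even
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += data
            indices.append(t)
            symbols.append(_CODE_TO_SYMBOL.get(code, "?"))
    return BeatAnnotationSet(np.asarray(indices, dtype=np.int64), symbols)


def _write_atr(path: Path, ann: BeatAnnotationSet) -> None:
    words = bytearray()
    prev = 0
    for idx, sym in zip(ann.r_indices, ann.symbols):
        code = _SYMBOL_TO_CODE.get(sym, 13)  # unknown beat if unmapped
        delta = int(idx) - prev
        prev = int(idx)
        if delta > 1023:
            words += struct.pack("<HHH", (_SKIP << 10),
                                 (delta >> 16) & 0xFFFF, delta & 0xFFFF)
            delta = 0
        words += struct.pack("<H", (code << 10) | delta)
    words += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(words))


# ---------------------------------------------------------------------------
# plain-text dialect
# ---------------------------------------------------------------------------


def _read_text_record(base: Path, meta: dict) -> EcgRecord:
    sig_path = base.with_suffix(".sig.csv")
    if not sig_path.exists():
        raise RecordIOError(f"missing signal file {sig_path}")
    signal = np.loadtxt(sig_path, delimiter=",", ndmin=2)
    return EcgRecord(
        record_id=base.name,
        signal=signal,
        fs=float(meta["fs"]),
        lead_names=list(meta["lead_names"]),
        source_db=meta.get("source_db", ""),
        provenance={"path": str(base), "dialect": "text"},
    )


def _read_text_annotations(path: Path) -> BeatAnnotationSet:
    indices, symbols = [], []
    for ln_no, ln in enumerate(path.read_text().splitlines()):
        ln = ln.strip()
        if not ln or ln.startswith("index"):
            continue
        parts = ln.split(",")
        if len(parts) != 2:
            raise FormatError(f"bad annotation line {ln_no} in {path}: {ln!r}")
        indices.append(int(parts[0]))
        symbols.append(parts[1])
    return BeatAnnotationSet(np.asarray(indices, dtype=np.int64), symbols)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def read_record(path, lead_priority: Sequence[str] = ()) -> EcgRecord:
    """Read a record (WFDB or text dialect) and select one lead.

    ``path`` is the record base path without extension.  The first lead
    in ``lead_priority`` that the record carries is selected; with no
    match (or an empty priority list) lead 0 is used.  Pass
    ``lead_priority=None`` to keep all leads.
    """
    base = Path(path)
    meta_path = base.with_suffix(".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        rec = _read_text_record(base, meta)
    elif base.with_suffix(".hea").exists():
        name, fs, n_samples, sigs = _read_header(base.with_suffix(".hea"))
        dat_path = base.parent / sigs[0]["file"]
        if not dat_path.exists():
            raise RecordIOError(f"missing signal file {dat_path}")
        if any(s["fmt"] != 212 for s in sigs):
            raise FormatError(
                f"unsupported signal format in {base}.hea (only 212 supported)"
            )
        adc = _unpack_212(dat_path.read_bytes(), n_samples * len(sigs))
        adc = adc.reshape(n_samples, len(sigs))
        gains = np.array([s["gain"] for s in sigs])
        baselines = np.array([s["baseline"] for s in sigs])
        signal = (adc - baselines) / gains
        rec = EcgRecord(
            record_id=name,
            signal=signal,
            fs=fs,
            lead_names=[s["desc"] for s in sigs],
            provenance={"path": str(base), "dialect": "wfdb",
                        "gain": [s["gain"] for s in sigs]},
        )
    else:
        raise RecordIOError(f"no record found at {base} (.hea or .meta.json)")
    if lead_priority is None:
        return rec
    return rec.select_lead(lead_priority)


def read_annotations(path) -> BeatAnnotationSet:
    """Read beat annotations (``.atr`` or ``.ann.csv``) for a record base path."""
    base = Path(path)
    csv_path = base.with_suffix(".ann.csv")
    if csv_path.exists():
        return _read_text_annotations(csv_path)
    atr_path = base.with_suffix(".atr")
    if atr_path.exists():
        return _read_atr(atr_path)
    raise RecordIOError(f"no annotations found at {base} (.atr or .ann.csv)")


def write_record(
    record: EcgRecord,
    annotations: BeatAnnotationSet,
    path,
    dialect: str = "wfdb",
    gain: float = DEFAULT_GAIN,
) -> None:
    """Write a record + annotations in the requested dialect.

    The WFDB dialect quantizes amplitudes to 1/gain mV steps (12-bit
    range); the text dialect stores full-precision decimals.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    if len(annotations) and int(annotations.r_indices[-1]) >= len(record):
        raise ValueError("annotation index beyond record length")
    try:
        if dialect == "wfdb":
            adc = np.round(record.signal * gain).astype(np.int64)
            if np.any((adc < -2048) | (adc > 2047)):
                raise ValueError(
                    "signal exceeds the 12-bit range at this gain; lower the gain"
                )
            lines = [f"{base.name} {record.n_leads} {record.fs:g} {len(record)}"]
            for j, lead in enumerate(record.lead_names):
                lines.append(
                    f"{base.name}.dat 212 {gain:g}(0)/mV 12 0 "
                    f"{int(adc[0, j])} 0 0 {lead}"
                )
            base.with_suffix(".hea").write_text("\n".join(lines) + "\n")
            base.with_suffix(".dat").write_bytes(_pack_212(adc.ravel()))
            _write_atr(base.with_suffix(".atr"), annotations)
        elif dialect == "text":
            np.savetxt(base.with_suffix(".sig.csv"), record.signal,
                       delimiter=",", fmt="%.6f")
            rows = ["index,symbol"] + [
                f"{int(i)},{s}"
                for i, s in zip(annotations.r_indices, annotations.symbols)
            ]
            base.with_suffix(".ann.csv").write_text("\n".join(rows) + "\n")
            base.with_suffix(".meta.json").write_text(
                json.dumps(
                    dict(
                        fs=record.fs,
                        lead_names=record.lead_names,
                        source_db=record.source_db,
                        gain=gain,
                    ),
                    indent=1,
                )
            )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except OSError as exc:
        raise RecordIOError(f"cannot write record at {base}: {exc}") from exc


def quantization_step(gain: float = DEFAULT_GAIN) -> float:
    """Round-trip amplitude error bound of the WFDB dialect, in mV."""
    return 0.5 / gain
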