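"""Multi-database merge: class-map construction, beat-level integration
of heterogeneous databases into one unified dataset, and the stratified
80/20 train/test split.

Databases differ in sampling frequency, leads and amplitude statistics;
integration extracts beats per database at its native rate, unifies
them at the target frequency, applies the chosen normalization, and
concatenates everything with per-beat provenance.  Per-class counts per
database are kept so the complementarity between sources stays visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .beats import DropLogEntry, WindowSpec, extract_beats
from .errors import ConfigurationError, IntegrationError
from .preprocessing import BeatDataset, preprocess_dataset
from .record_io import BeatAnnotationSet, EcgRecord, read_annotations, read_record

N_CLASSES = 16


@dataclass
class ClassMap:
    """Bijection from single-character beat codes onto class ids 0–15."""

    code_to_id: dict[str, int]
    id_to_abbr: dict[int, str]
    id_to_name: dict[int, str]
    excluded_codes: frozenset[str] = frozenset()
    scheme: str = "custom"

    def __post_init__(self):
        ids = sorted(self.code_to_id.values())
        if len(ids) != len(set(ids)):
            raise ConfigurationError("two codes map to the same class id")
        if set(self.code_to_id) & set(self.excluded_codes):
            raise ConfigurationError("mapped and excluded code sets overlap")
        self.excluded_codes = frozenset(self.excluded_codes)

    @property
    def n_classes(self) -> int:
        return len(self.code_to_id)

    def label_for(self, symbol: str) -> Optional[int]:
        """Class id for a beat code, or None (excluded/unknown → skip)."""
        return self.code_to_id.get(symbol)

    def abbr(self, class_id: int) -> str:
        return self.id_to_abbr.get(class_id, str(class_id))


def build_class_map(scheme: str = "hercules16", path=None) -> ClassMap:
    """Load a named class scheme (or a user YAML file via ``path``).

    The default 16-class scheme keeps the fine-grained beat types and
    drops parent classes that subsume retained subclasses.
    """
    if path is not None:
        text = Path(path).read_text()
    elif scheme == "hercules16":
        text = (resources.files("ecgfuse") / "data" / "hercules16.yaml").read_text()
    else:
        raise ConfigurationError(f"unknown class scheme {scheme!r}")
    doc = yaml.safe_load(text)
    classes = doc["classes"]
    codes = [c["code"] for c in classes]
    if len(codes) != len(set(codes)):
        raise ConfigurationError("duplicate beat code in class scheme")
    cmap = ClassMap(
        code_to_id={c["code"]: int(c["id"]) for c in classes},
        id_to_abbr={int(c["id"]): c.get("abbr", c["code"]) for c in classes},
        id_to_name={int(c["id"]): c.get("name", c["code"]) for c in classes},
        excluded_codes=frozenset(doc.get("excluded_codes", [])),
        scheme=doc.get("scheme", scheme),
    )
    ids = sorted(cmap.code_to_id.values())
    if ids != list(range(len(ids))):
        raise ConfigurationError("class ids must be 0..n_classes-1")
    return cmap


@dataclass
class DatabaseSource:
    """One database's contribution: in-memory records or on-disk paths."""

    name: str
    records: Sequence[tuple[EcgRecord, BeatAnnotationSet]] = ()
    record_paths: Sequence = ()
    lead_priority: Sequence[str] = ()

    def iter_records(self):
        for rec, ann in self.records:
            if rec.n_leads > 1:
                rec = rec.select_lead(self.lead_priority)
            if not rec.source_db:
                rec.source_db = self.name
            yield rec, ann
        for p in self.record_paths:
            rec = read_record(p, self.lead_priority)
            rec.source_db = rec.source_db or self.name
            yield rec, read_annotations(p)


@dataclass
class IntegrationResult:
    dataset: BeatDataset
    counts: pd.DataFrame  # class x database beat counts (+ merged column)
    drop_log: list[DropLogEntry]
    skipped_symbols: dict[str, int]
    preprocess_log: pd.DataFrame


def integrate(
    databases: Sequence[DatabaseSource],
    window: WindowSpec = WindowSpec(),
    class_map: Optional[ClassMap] = None,
    preprocessor: str = "self",
) -> IntegrationResult:
    """Merge databases into one preprocessed unified BeatDataset.

    Every emitted beat has exactly ``window.L`` samples at
    ``window.fs_target`` Hz regardless of source rate.  Boundary drops
    are logged; unmapped annotation symbols are counted per symbol.
    """
    if not databases:
        raise IntegrationError("no databases to integrate")
    if class_map is None:
        class_map = build_class_map()
    all_beats = []
    drop_log: list[DropLogEntry] = []
    skipped: dict[str, int] = {}
    for db in databases:
        for rec, ann in db.iter_records():
            beats, dropped = extract_beats(rec, ann, window, class_map)
            all_beats.extend(beats)
            drop_log.extend(dropped)
            for sym in ann.symbols:
                if class_map.label_for(sym) is None:
                    skipped[sym] = skipped.get(sym, 0) + 1
    if not all_beats:
        raise IntegrationError("integration produced no mappable beats")
    dataset = BeatDataset.from_heartbeats(all_beats)
    dataset, pre_log = preprocess_dataset(dataset, preprocessor)
    counts = per_class_counts(dataset, class_map, [db.name for db in databases])
    return IntegrationResult(dataset, counts, drop_log, skipped, pre_log)


def per_class_counts(
    dataset: BeatDataset, class_map: ClassMap, db_names: Sequence[str]
) -> pd.DataFrame:
    """Class-by-database beat count table with a merged total column."""
    rows = []
    dbs = dataset.provenance["source_db"].to_numpy()
    for cid in range(class_map.n_classes):
        in_class = dataset.labels == cid
        row = {"class_id": cid, "abbr": class_map.abbr(cid)}
        for name in db_names:
            row[name] = int(np.sum(in_class & (dbs == name)))
        row["merged"] = int(in_class.sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------


@dataclass
class SplitResult:
    train: BeatDataset
    test: BeatDataset
    per_class_counts: pd.DataFrame  # class_id, total, train, test
    seed: int
    test_fraction: float


def stratified_split(
    dataset: BeatDataset, test_fraction: float = 0.2, seed: int = 0
) -> SplitResult:
    """Seeded per-class split conserving every class's total count.

    A class of m_c >= 2 members contributes ``max(1, floor(test_fraction
    * m_c))`` test beats (so every multi-member class is represented in
    the test set); singleton classes stay wholly in training.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    train_idx, test_idx = [], []
    rows = []
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        m_c = len(members)
        n_test = max(1, int(np.floor(test_fraction * m_c))) if m_c >= 2 else 0
        perm = rng.permutation(members)
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
        rows.append(
            {"class_id": int(cid), "total": m_c, "train": m_c - n_test, "test": n_test}
        )
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], int)
    return SplitResult(
        train=dataset.subset(train_idx),
        test=dataset.subset(test_idx),
        per_class_counts=pd.DataFrame(rows),
        seed=seed,
        test_fraction=test_fraction,
    )


# ---------------------------------------------------------------------------
# persistence + annotation counting
# ---------------------------------------------------------------------------


def save_dataset(dataset: BeatDataset, path, meta: Optional[dict] = None) -> None:
    """One beat per CSV row: n amplitudes, label, source_db, source_record."""
    path = Path(path)
    n = dataset.n_samples_per_beat
    df = pd.DataFrame(dataset.A, columns=[f"s{j}" for j in range(n)])
    df["label"] = dataset.labels
    df["source_db"] = dataset.provenance["source_db"].to_numpy()
    df["source_record"] = dataset.provenance["source_record"].to_numpy()
    df.to_csv(path, index=False)
    if meta is not None:
        Path(path).with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def load_dataset(path) -> BeatDataset:
    df = pd.read_csv(path)
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    return BeatDataset(
        A=df[sample_cols].to_numpy(dtype=np.float64),
        labels=df["label"].to_numpy(dtype=np.int64),
        provenance=df[["source_db", "source_record"]],
    )


def count_annotations(record_paths: Sequence, class_map: Optional[ClassMap] = None):
    """Tally beat annotations across records (per class + total).

    Pointed at a full arrhythmia database this reproduces its published
    per-class beat counts; unmapped symbols are tallied separately.
    """
    if class_map is None:
        class_map = build_class_map()
    per_class = {cid: 0 for cid in range(class_map.n_classes)}
    unmapped: dict[str, int] = {}
    total_beats = 0
    for p in record_paths:
        ann = read_annotations(p)
        for sym in ann.symbols:
            cid = class_map.label_for(sym)
            if cid is None:
                unmapped[sym] = unmapped.get(sym, 0) + 1
            else:
                per_class[cid] += 1
                total_beats += 1
    return {"per_class": per_class, "total_beats": total_beats, "unmapped": unmapped}
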