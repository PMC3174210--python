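"""FASTA I/O, benchmark-style screening filters, and synthetic data.

Labels travel either as a trailing ``|1`` / ``|0`` token on the FASTA
header id (1 = binding) or as a two-column ``id<TAB>label`` sidecar TSV;
both dialects are read and written here.

The screening filters mirror a typical benchmark construction: drop
sequences shorter than 50 residues, drop sequences with more than 10
consecutive ``X``, and greedily enforce a pairwise-identity ceiling as a
self-contained stand-in for an external culling service.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from greybind.encoding import STANDARD_RESIDUES

BINDING = "binding"
NON_BINDING = "non-binding"

_LABEL_TO_TOKEN = {BINDING: "1", NON_BINDING: "0"}
_TOKEN_TO_LABEL = {"1": BINDING, "0": NON_BINDING}


class FastaParseError(ValueError):
    """Malformed FASTA input; message carries the line number."""


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence with an accession id and an optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if self.label not in (None, BINDING, NON_BINDING):
            raise ValueError(f"record {self.id!r} has invalid label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LabeledDataset:
    """A list of uniquely-identified records, all labeled."""

    records: tuple[ProteinRecord, ...]
    class_counts: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r}")
        counts: dict[str, int] = {}
        for r in records:
            if r.label is None:
                raise ValueError(f"record {r.id!r} is unlabeled")
            counts[r.label] = counts.get(r.label, 0) + 1
        object.__setattr__(self, "class_counts", counts)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset(tuple(self.records[i] for i in indices))


def _split_header(header: str) -> tuple[str, str | None]:
    """Parse ``>id[|label] free text`` -> (id, label or None)."""
    token = header.split()[0] if header.split() else ""
    label = None
    if "|" in token:
        head, _, tail = token.rpartition("|")
        if tail in _TOKEN_TO_LABEL and head:
            return head, _TOKEN_TO_LABEL[tail]
    return token, label


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read FASTA records; ids are headers up to the first whitespace.

    A trailing ``|1`` / ``|0`` on the id token becomes the record label.

    Raises
    ------
    FastaParseError
        Empty file, text before the first header, a header with no
        sequence, an empty id, or a duplicate id.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header_line = 0
    current: tuple[str, str | None] | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current is None:
            return
        rid, label = current
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"{path}:{header_line}: header {rid!r} has no sequence")
        if rid in seen:
            raise FastaParseError(f"{path}:{header_line}: duplicate id {rid!r}")
        seen.add(rid)
        records.append(ProteinRecord(id=rid, sequence=seq, label=label))

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rid, label = _split_header(line[1:])
                if not rid:
                    raise FastaParseError(f"{path}:{lineno}: empty header id")
                current = (rid, label)
                chunks = []
                header_line = lineno
            else:
                if current is None:
                    raise FastaParseError(f"{path}:{lineno}: sequence data before any header")
                chunks.append(line)
    flush()
    if not records:
        raise FastaParseError(f"{path}:1: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, embedding labels as ``|1`` / ``|0`` tokens."""
    with open(path, "w", encoding="utf-8") as fh:
        for record in records:
            rid = record.id
            if record.label is not None:
                rid = f"{rid}|{_LABEL_TO_TOKEN[record.label]}"
            fh.write(f">{rid}\n")
            for start in range(0, len(record.sequence), width):
                fh.write(record.sequence[start:start + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>label`` sidecar; labels are 1/0 or the label names."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rid, raw = parts
            label = _TOKEN_TO_LABEL.get(raw, raw)
            if label not in (BINDING, NON_BINDING):
                raise ValueError(f"{path}:{lineno}: invalid label {raw!r}")
            if rid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {rid!r}")
            labels[rid] = label
    return labels


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\n")
        for record in records:
            if record.label is None:
                raise ValueError(f"record {record.id!r} is unlabeled")
            fh.write(f"{record.id}\t{_LABEL_TO_TOKEN[record.label]}\n")


def attach_labels(records: Sequence[ProteinRecord], labels: Mapping[str, str]) -> LabeledDataset:
    """Combine records with a sidecar label mapping into a LabeledDataset."""
    out = []
    for record in records:
        label = labels.get(record.id, record.label)
        if label is None:
            raise ValueError(f"no label for record {record.id!r}")
        out.append(replace(record, label=label))
    return LabeledDataset(tuple(out))


# ---------------------------------------------------------------------------
# screening filters


def filter_min_length(
    records: Sequence[ProteinRecord], min_len: int = 50
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into (length >= min_len, shorter)."""
    kept = [r for r in records if len(r) >= min_len]
    removed = [r for r in records if len(r) < min_len]
    return kept, removed


def _longest_x_run(sequence: str) -> int:
    runs = re.findall(r"X+", sequence.upper())
    return max((len(run) for run in runs), default=0)


def filter_x_runs(
    records: Sequence[ProteinRecord], max_run: int = 10
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Drop records whose longest consecutive run of X exceeds ``max_run``."""
    kept = [r for r in records if _longest_x_run(r.sequence) <= max_run]
    removed = [r for r in records if _longest_x_run(r.sequence) > max_run]
    return kept, removed


def _make_aligner() -> Align.PairwiseAligner:
    # global alignment; BLAST-like scores, documented convention:
    # identity = identical columns / alignment length (incl. gap columns)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches over alignment length."""
    if aligner is None:
        aligner = _make_aligner()
    alignment = aligner.align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length if length else 0.0


def greedy_identity_filter(
    records: Sequence[ProteinRecord], max_identity: float = 0.25
) -> list[ProteinRecord]:
    """Greedy redundancy reduction in input order.

    A record is kept iff its identity to every previously kept record is
    at most ``max_identity``.  Deterministic for a fixed input order.
    """
    aligner = _make_aligner()
    kept: list[ProteinRecord] = []
    for record in records:
        if all(
            pairwise_identity(record.sequence, other.sequence, aligner) <= max_identity
            for other in kept
        ):
            kept.append(record)
    return kept


# ---------------------------------------------------------------------------
# synthetic data

#: Positive-class default: lysine/arginine-enriched (DNA-binder charge bias).
_ENRICHED = {"K": 0.18, "R": 0.18}


def default_profiles() -> dict[str, np.ndarray]:
    """Default per-class residue-frequency profiles."""
    uniform = np.full(20, 0.05)
    enriched = np.full(20, (1.0 - sum(_ENRICHED.values())) / 18)
    for residue, freq in _ENRICHED.items():
        enriched[STANDARD_RESIDUES.index(residue)] = freq
    return {BINDING: enriched, NON_BINDING: uniform}


def generate_synthetic(
    n_per_class: int,
    length_range: tuple[int, int] = (50, 150),
    bias: Mapping[str, np.ndarray] | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Draw a labeled two-class dataset with per-class residue profiles.

    Each sequence position is i.i.d. from the class profile; lengths are
    uniform over ``length_range`` (inclusive).  Reproducible for a fixed
    seed.

    Raises
    ------
    ValueError
        Non-positive class size, min length below 50, or a profile that
        is not a distribution over the 20 residues.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    min_len, max_len = length_range
    if min_len < 50:
        raise ValueError("minimum synthetic length is 50 (benchmark screening floor)")
    if max_len < min_len:
        raise ValueError("length_range must satisfy min <= max")
    profiles = dict(default_profiles() if bias is None else bias)
    for label in (BINDING, NON_BINDING):
        profile = np.asarray(profiles[label], dtype=float)
        if profile.shape != (20,) or np.any(profile < 0) or abs(profile.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile for {label!r} is not a distribution over 20 residues")
        profiles[label] = profile

    rng = np.random.default_rng(seed)
    alphabet = np.array(list(STANDARD_RESIDUES))
    records: list[ProteinRecord] = []
    for label, prefix in ((BINDING, "POS"), (NON_BINDING, "NEG")):
        for i in range(n_per_class):
            length = int(rng.integers(min_len, max_len + 1))
            seq = "".join(rng.choice(alphabet, size=length, p=profiles[label]))
            records.append(ProteinRecord(id=f"{prefix}{i + 1:04d}", sequence=seq, label=label))
    return LabeledDataset(tuple(records))
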