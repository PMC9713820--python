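"""Sequence I/O: FASTA reading, precursor/mature pairing, k-mer tokenization.

Precursor (hairpin) and mature miRNA sequences arrive as miRBase-style FASTA;
a three-column TSV (``precursor_id  mature_ids  label``) declares which mature
sequences belong to which precursor and carries the binary essentiality label.
Mature miRNAs are located inside their precursor by exact substring search,
since a mature miRNA is by definition a sub-sequence of its hairpin precursor.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

RNA_ALPHABET = frozenset("AUCG")

__all__ = [
    "RNASequence",
    "MatureInterval",
    "PreMiRNARecord",
    "TokenSequence",
    "normalize_sequence",
    "read_fasta",
    "pair_precursor_matures",
    "tokenize_kmers",
    "load_benchmark",
    "write_fasta",
    "write_mapping",
]


class SequenceError(ValueError):
    """Raised for malformed sequences, FASTA files or mapping tables."""


@dataclass(frozen=True)
class RNASequence:
    """An identified RNA sequence over {A, U, C, G}."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise SequenceError(
                f"sequence {self.id!r}: invalid character {self.residues[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MatureInterval:
    """Location of a mature miRNA within its precursor (0-based, half-open)."""

    start: int
    end: int
    mature_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise SequenceError(
                f"mature {self.mature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.end - self.start < 15:
            raise SequenceError(
                f"mature {self.mature_id!r}: interval length {self.end - self.start} "
                "is below the 15 nt sanity floor for a mature miRNA"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PreMiRNARecord:
    """A precursor with its mature arm(s) and an optional essentiality label."""

    precursor: RNASequence
    matures: tuple[MatureInterval, ...]
    label: int | None = None

    def __post_init__(self):
        if not 1 <= len(self.matures) <= 2:
            raise SequenceError(
                f"precursor {self.precursor.id!r}: expected 1 or 2 mature arms, "
                f"got {len(self.matures)}"
            )
        ivs = sorted(self.matures, key=lambda m: m.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise SequenceError(
                    f"precursor {self.precursor.id!r}: overlapping mature intervals "
                    f"{a.mature_id!r} and {b.mature_id!r}"
                )
        for m in self.matures:
            if m.end > len(self.precursor):
                raise SequenceError(
                    f"precursor {self.precursor.id!r}: mature {m.mature_id!r} "
                    "extends past the precursor"
                )
        if self.label is not None and self.label not in (0, 1):
            raise SequenceError(
                f"precursor {self.precursor.id!r}: label must be 0 or 1, got {self.label}"
            )

    def mature_sequences(self) -> list[str]:
        """Mature sub-sequences in 5'→3' order of their position."""
        return [
            self.precursor.residues[m.start : m.end]
            for m in sorted(self.matures, key=lambda m: m.start)
        ]


@dataclass(frozen=True)
class TokenSequence:
    """Overlapping k-mer tokens of a sequence, stride 1."""

    tokens: tuple[str, ...]
    k: int

    def __len__(self) -> int:
        return len(self.tokens)


def normalize_sequence(raw: str, id: str) -> RNASequence:
    """Uppercase, strip whitespace, convert DNA T→U, validate the alphabet."""
    if not raw or not raw.strip():
        raise SequenceError(f"sequence {id!r} is empty")
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    return RNASequence(id=id, residues=cleaned)


def read_fasta(path: str | Path) -> list[RNASequence]:
    """Read a FASTA file into normalized :class:`RNASequence` records.

    The first whitespace-delimited token of each header is the ID.  Duplicate
    IDs and empty files are rejected.  CRLF line endings are tolerated.
    """
    path = Path(path)
    text = path.read_text().replace("\r\n", "\n")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out: list[RNASequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append(normalize_sequence(str(rec.seq), rec.id))
    return out


def write_fasta(path: str | Path, seqs: Sequence[RNASequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def pair_precursor_matures(
    precursors: Sequence[RNASequence],
    matures: Sequence[RNASequence],
    mapping: Mapping[str, Sequence[str]],
    labels: Mapping[str, int] | None = None,
) -> list[PreMiRNARecord]:
    """Locate each mapped mature miRNA inside its precursor by substring search.

    The leftmost occurrence is used when a mature sequence occurs more than
    once.  A mature that is not a substring of its precursor, or more than two
    matures mapped to one precursor, is an error.
    """
    pre_by_id = {p.id: p for p in precursors}
    mat_by_id = {m.id: m for m in matures}
    labels = labels or {}
    records: list[PreMiRNARecord] = []
    for pre_id in mapping:
        if pre_id not in pre_by_id:
            raise SequenceError(f"mapping references unknown precursor {pre_id!r}")
        pre = pre_by_id[pre_id]
        mat_ids = list(mapping[pre_id])
        if len(mat_ids) > 2:
            raise SequenceError(
                f"precursor {pre_id!r}: {len(mat_ids)} matures mapped (max 2: 5p/3p)"
            )
        intervals = []
        for mid in mat_ids:
            if mid not in mat_by_id:
                raise SequenceError(f"mapping references unknown mature {mid!r}")
            mseq = mat_by_id[mid].residues
            start = pre.residues.find(mseq)
            if start < 0:
                raise SequenceError(
                    f"mature {mid!r} is not a substring of precursor {pre_id!r}"
                )
            intervals.append(MatureInterval(start, start + len(mseq), mid))
        records.append(
            PreMiRNARecord(
                precursor=pre,
                matures=tuple(intervals),
                label=labels.get(pre_id),
            )
        )
    return records


def tokenize_kmers(seq: RNASequence | str, k: int) -> TokenSequence:
    """Split a sequence into overlapping k-mers with stride 1.

    ``"AUUGUCC"`` at k=3 yields ``AUU, UUG, UGU, GUC, UCC`` — |S| − k + 1
    tokens in total.
    """
    residues = seq.residues if isinstance(seq, RNASequence) else seq
    if k < 1:
        raise SequenceError(f"k must be >= 1, got {k}")
    if len(residues) < k:
        raise SequenceError(
            f"sequence of length {len(residues)} is shorter than k={k}"
        )
    toks = tuple(residues[i : i + k] for i in range(len(residues) - k + 1))
    return TokenSequence(tokens=toks, k=k)


def _read_mapping_tsv(path: str | Path):
    path = Path(path)
    text = path.read_text().replace("\r\n", "\n")
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    required = {"precursor_id", "mature_ids", "label"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise SequenceError(
            f"{path}: mapping TSV must have columns precursor_id, mature_ids, label"
        )
    mapping: dict[str, list[str]] = {}
    labels: dict[str, int] = {}
    for row in reader:
        pid = row["precursor_id"].strip()
        if pid in mapping:
            raise SequenceError(f"{path}: duplicate precursor {pid!r} in mapping")
        mapping[pid] = [m.strip() for m in row["mature_ids"].split(";") if m.strip()]
        raw_label = row["label"].strip()
        if raw_label not in ("0", "1"):
            raise SequenceError(
                f"{path}: label for {pid!r} must be 0 or 1, got {raw_label!r}"
            )
        labels[pid] = int(raw_label)
    return mapping, labels


def write_mapping(path: str | Path, records: Sequence[PreMiRNARecord]) -> None:
    with open(path, "w") as fh:
        fh.write("precursor_id\tmature_ids\tlabel\n")
        for r in records:
            mids = ";".join(m.mature_id for m in r.matures)
            fh.write(f"{r.precursor.id}\t{mids}\t{r.label}\n")


def load_benchmark(
    precursor_fasta: str | Path,
    mature_fasta: str | Path,
    mapping_tsv: str | Path,
) -> list[PreMiRNARecord]:
    """Load a labeled precursor/mature benchmark from FASTA + mapping TSV."""
    precursors = read_fasta(precursor_fasta)
    matures = read_fasta(mature_fasta)
    mapping, labels = _read_mapping_tsv(mapping_tsv)
    return pair_precursor_matures(precursors, matures, mapping, labels)
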