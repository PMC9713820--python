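"""The 38-dimensional statistic-and-structure feature vector F_s.

For each precursor/mature record the vector concatenates, in fixed order:

====================  ====  =========================================================
block                 dim   contents
====================  ====  =========================================================
pre_content            3    U, C, G fractions in the precursor
mat_content            3    U, C, G fractions in the mature arm(s)
nonmat_content         3    U, C, G fractions in the non-mature remainder
mat_length             1    total mature residues
nonmat_length          1    precursor length − mature residues
cleavage_class         1    1 all arms start with U / −1 none do / 0 mixed
pre_dinuc              9    UU,UC,UG,CU,CC,CG,GU,GC,GG counts in the precursor
mat_dinuc              9    same counts in the mature arm(s), no junction pair
mfe_block              2    MFE, nMFE = MFE/L
bp_block               6    dP, dP/L, dQ, dQ/L, dD, dD/L
====================  ====  =========================================================

Adenine never appears in the content/dinucleotide blocks (it only contributes
to denominators): with the fourth base determined by the other three, the
A-containing statistics are redundant.  For two-arm precursors the mature
blocks are computed over the concatenation of both arms, keeping the
dimensionality fixed; dinucleotide counting skips the artificial junction
between arms.

Standardization is a per-dimension z-score fit on training folds only;
zero-variance dimensions pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seq_io import PreMiRNARecord, RNASequence
from .structure import FoldMetrics

STATIC_DIM = 38

DINUCLEOTIDES = ("UU", "UC", "UG", "CU", "CC", "CG", "GU", "GC", "GG")

#: TSV column names, block_name.index
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"pre_content.{b}" for b in "UCG")
    + tuple(f"mat_content.{b}" for b in "UCG")
    + tuple(f"nonmat_content.{b}" for b in "UCG")
    + ("mat_length.0", "nonmat_length.0", "cleavage_class.0")
    + tuple(f"pre_dinuc.{d}" for d in DINUCLEOTIDES)
    + tuple(f"mat_dinuc.{d}" for d in DINUCLEOTIDES)
    + ("mfe_block.mfe", "mfe_block.nmfe")
    + tuple(f"bp_block.{n}" for n in ("dP", "dP_L", "dQ", "dQ_L", "dD", "dD_L"))
)
assert len(FEATURE_NAMES) == STATIC_DIM

__all__ = [
    "STATIC_DIM",
    "FEATURE_NAMES",
    "StaticFeatureVector",
    "StandardizerStats",
    "base_content",
    "dinucleotide_counts",
    "non_mature_sequence",
    "cleavage_site_class",
    "static_feature_vector",
    "feature_matrix",
    "fit_standardizer",
    "apply_standardizer",
]


@dataclass(frozen=True)
class StaticFeatureVector:
    pre_content: tuple[float, float, float]
    mat_content: tuple[float, float, float]
    nonmat_content: tuple[float, float, float]
    mat_length: float
    nonmat_length: float
    cleavage_class: int
    pre_dinuc: tuple[int, ...]
    mat_dinuc: tuple[int, ...]
    mfe_block: tuple[float, float]
    bp_block: tuple[float, ...]

    def __post_init__(self):
        if len(self.pre_dinuc) != 9 or len(self.mat_dinuc) != 9:
            raise ValueError("dinucleotide blocks must have 9 entries")
        if len(self.bp_block) != 6:
            raise ValueError("bp block must have 6 entries")
        if self.cleavage_class not in (-1, 0, 1):
            raise ValueError("cleavage class must be in {-1, 0, 1}")

    def to_array(self) -> np.ndarray:
        v = np.array(
            self.pre_content
            + self.mat_content
            + self.nonmat_content
            + (self.mat_length, self.nonmat_length, float(self.cleavage_class))
            + tuple(float(c) for c in self.pre_dinuc)
            + tuple(float(c) for c in self.mat_dinuc)
            + self.mfe_block
            + self.bp_block,
            dtype=np.float64,
        )
        assert v.shape == (STATIC_DIM,)
        return v


def base_content(seq: RNASequence | str) -> tuple[float, float, float]:
    """U, C, G fractions; A counts only in the denominator. Empty input → zeros."""
    residues = seq.residues if isinstance(seq, RNASequence) else seq
    if not residues:
        return (0.0, 0.0, 0.0)
    n = len(residues)
    return (
        residues.count("U") / n,
        residues.count("C") / n,
        residues.count("G") / n,
    )


def dinucleotide_counts(seq: RNASequence | str) -> tuple[int, ...]:
    """Overlapping adjacent-pair counts; pairs containing A are ignored."""
    residues = seq.residues if isinstance(seq, RNASequence) else seq
    if len(residues) < 2:
        raise ValueError("dinucleotide counting needs a sequence of length >= 2")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(residues) - 1):
        pair = residues[i : i + 2]
        if pair in counts:
            counts[pair] += 1
    return tuple(counts[d] for d in DINUCLEOTIDES)


def non_mature_sequence(record: PreMiRNARecord) -> str:
    """Precursor with all mature intervals excised, segments joined 5'→3'."""
    residues = record.precursor.residues
    cut = sorted(record.matures, key=lambda m: m.start)
    pieces = []
    pos = 0
    for m in cut:
        pieces.append(residues[pos : m.start])
        pos = m.end
    pieces.append(residues[pos:])
    return "".join(pieces)


def cleavage_site_class(record: PreMiRNARecord) -> int:
    """Whether the 5'-most nucleotide of every mature arm is U (1/−1/0 mixed)."""
    firsts = [record.precursor.residues[m.start] for m in record.matures]
    is_u = [c == "U" for c in firsts]
    if all(is_u):
        return 1
    if not any(is_u):
        return -1
    return 0


def _multi_arm_dinuc(arms: Sequence[str]) -> tuple[int, ...]:
    # summed per-arm so the junction between concatenated arms is not counted
    totals = np.zeros(9, dtype=np.int64)
    for arm in arms:
        totals += np.array(dinucleotide_counts(arm), dtype=np.int64)
    return tuple(int(x) for x in totals)


def static_feature_vector(record: PreMiRNARecord, metrics: FoldMetrics) -> StaticFeatureVector:
    """Assemble F_s for one record from sequence statistics and fold metrics."""
    arms = record.mature_sequences()
    mature_concat = "".join(arms)
    nonmat = non_mature_sequence(record)
    return StaticFeatureVector(
        pre_content=base_content(record.precursor),
        mat_content=base_content(mature_concat),
        nonmat_content=base_content(nonmat),
        mat_length=float(len(mature_concat)),
        nonmat_length=float(len(record.precursor) - len(mature_concat)),
        cleavage_class=cleavage_site_class(record),
        pre_dinuc=dinucleotide_counts(record.precursor),
        mat_dinuc=_multi_arm_dinuc(arms),
        mfe_block=(metrics.mfe, metrics.nmfe),
        bp_block=(
            metrics.dP,
            metrics.dP_L,
            metrics.dQ,
            metrics.dQ_L,
            metrics.dD,
            metrics.dD_L,
        ),
    )


def feature_matrix(records: Sequence[PreMiRNARecord], engine=None) -> np.ndarray:
    """Stack F_s for many records into an (N, 38) matrix (engine-agnostic)."""
    from .structure import compute_fold_metrics

    rows = []
    for rec in records:
        metrics = compute_fold_metrics(rec.precursor, engine)
        rows.append(static_feature_vector(rec, metrics).to_array())
    return np.vstack(rows) if rows else np.empty((0, STATIC_DIM))


@dataclass(frozen=True)
class StandardizerStats:
    mean: np.ndarray
    std: np.ndarray  # zero-variance dimensions carry std = 1 (pass-through)


def fit_standardizer(vectors: np.ndarray | Sequence[StaticFeatureVector]) -> StandardizerStats:
    """Per-dimension z-score statistics; fit on training folds only."""
    if not isinstance(vectors, np.ndarray):
        vectors = np.vstack([v.to_array() for v in vectors]) if len(vectors) else np.empty((0, STATIC_DIM))
    if vectors.shape[0] < 2:
        raise ValueError("standardizer needs at least 2 training vectors")
    mean = vectors.mean(axis=0)
    std = vectors.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    # pass zero-variance dims through unchanged (mean shift would zero them out,
    # losing e.g. a constant cleavage class; keep the raw value instead)
    mean = np.where(vectors.std(axis=0) < 1e-12, 0.0, mean)
    return StandardizerStats(mean=mean, std=std)


def apply_standardizer(
    vector: np.ndarray | StaticFeatureVector, stats: StandardizerStats
) -> np.ndarray:
    v = vector.to_array() if isinstance(vector, StaticFeatureVector) else np.asarray(vector, dtype=np.float64)
    return (v - stats.mean) / stats.std
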