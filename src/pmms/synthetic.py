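"""Seeded synthetic pre-miRNA datasets with controllable class separation.

Each record is a hairpin-shaped precursor: a 5' stem drawn with a
class-specific GC probability, a short unpaired loop, and a 3' stem that is
the exact reverse complement of the 5' stem (so the built-in folding engine
always finds a deep stem).  A-rich flanks pad the precursor into the
realistic 60–120 nt length range.  One mature interval (~20–24 nt) sits on
the 5' arm; its first nucleotide is forced to U with a class-specific
probability, driving the cleavage-site-class feature.

The two classes ("essential" label 1 vs "non-essential" label 0) differ only
through these controllable knobs — stem GC content and the U-start
probability — both of which are visible to the handcrafted feature extractor
(contents, dinucleotides, structure metrics, cleavage class) and to the
sequence encoder, so the full pipeline is exercised.  The ``effect`` presets
give a strongly separable, weakly separable, or null (identical classes)
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_io import (
    MatureInterval,
    PreMiRNARecord,
    RNASequence,
    write_fasta,
    write_mapping,
)

__all__ = [
    "SynthConfig",
    "HairpinParts",
    "generate_hairpin",
    "generate_dataset",
    "write_dataset",
    "EFFECTS",
]

_COMPLEMENT = str.maketrans("AUCG", "UAGC")

#: per-class (gc, u_start) presets for the class-separation strength
EFFECTS: dict[str, dict[str, float]] = {
    "strong": {"gc_pos": 0.70, "gc_neg": 0.45, "u_start_pos": 0.9, "u_start_neg": 0.3},
    "weak": {"gc_pos": 0.60, "gc_neg": 0.50, "u_start_pos": 0.7, "u_start_neg": 0.5},
    "none": {"gc_pos": 0.55, "gc_neg": 0.55, "u_start_pos": 0.6, "u_start_neg": 0.6},
}


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 77
    n_neg: int = 77
    stem_len: tuple[int, int] = (18, 30)  # inclusive range
    loop_len: tuple[int, int] = (4, 10)
    mature_len: tuple[int, int] = (20, 24)
    gc_pos: float = 0.70
    gc_neg: float = 0.45
    u_start_pos: float = 0.9
    u_start_neg: float = 0.3
    min_total: int = 60
    max_total: int = 120
    seed: int = 0

    def __post_init__(self):
        for p in (self.gc_pos, self.gc_neg, self.u_start_pos, self.u_start_neg):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (self.stem_len, self.loop_len, self.mature_len):
            if lo > hi or lo < 1:
                raise ValueError("ranges must be non-empty and positive")
        if not self.min_total <= self.max_total:
            raise ValueError("invalid total-length window")

    @classmethod
    def with_effect(cls, effect: str, **kwargs) -> "SynthConfig":
        if effect not in EFFECTS:
            raise ValueError(f"unknown effect {effect!r}; choose from {sorted(EFFECTS)}")
        return cls(**{**EFFECTS[effect], **kwargs})


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _draw_stem(rng: np.random.Generator, n: int, gc: float) -> str:
    # GC with probability gc, AU otherwise; uniform within each pair class
    strong = rng.random(n) < gc
    gcs = rng.choice(list("GC"), size=n)
    aus = rng.choice(list("AU"), size=n)
    return "".join(np.where(strong, gcs, aus))


def _draw_flank(rng: np.random.Generator, n: int) -> str:
    # A-rich so flanks rarely pair with the stem
    return "".join(rng.choice(list("AUCG"), size=n, p=[0.7, 0.1, 0.1, 0.1]))


@dataclass(frozen=True)
class HairpinParts:
    """Anatomy of one generated hairpin (5'→3'): flank, stem, loop, stem', flank."""

    flank5: str
    stem5: str
    loop: str
    stem3: str
    flank3: str
    mature_start: int
    mature_len: int


def generate_hairpin(
    rng: np.random.Generator,
    config: SynthConfig,
    label: int,
    record_id: str,
    return_parts: bool = False,
) -> PreMiRNARecord | tuple[PreMiRNARecord, HairpinParts]:
    """One labeled hairpin record under the class parameters for ``label``."""
    gc = config.gc_pos if label == 1 else config.gc_neg
    u_start = config.u_start_pos if label == 1 else config.u_start_neg

    stem_n = int(rng.integers(config.stem_len[0], config.stem_len[1] + 1))
    loop_n = int(rng.integers(config.loop_len[0], config.loop_len[1] + 1))
    core = 2 * stem_n + loop_n
    total = int(rng.integers(max(config.min_total, core), config.max_total + 1))
    extra = max(0, total - core)
    f5 = extra // 2
    f3 = extra - f5

    left = list(_draw_stem(rng, stem_n, gc))
    loop = "".join(rng.choice(list("AUCG"), size=loop_n))

    # mature arm on the 5' stem, possibly running into the loop
    mat_n = min(int(rng.integers(config.mature_len[0], config.mature_len[1] + 1)), stem_n + loop_n)
    mat_off = int(rng.integers(0, stem_n + loop_n - mat_n + 1)) if stem_n + loop_n > mat_n else 0
    mat_off = min(mat_off, 2)  # Drosha cuts near the stem base
    if rng.random() < u_start:
        first = "U"
    else:
        first = str(rng.choice(list("ACG")))
    arm = left + list(loop)
    arm[mat_off] = first
    left = arm[:stem_n]
    loop = "".join(arm[stem_n:])

    left_s = "".join(left)
    parts = HairpinParts(
        flank5=_draw_flank(rng, f5),
        stem5=left_s,
        loop=loop,
        stem3=_revcomp(left_s),
        flank3=_draw_flank(rng, f3),
        mature_start=f5 + mat_off,
        mature_len=mat_n,
    )
    precursor = parts.flank5 + parts.stem5 + parts.loop + parts.stem3 + parts.flank3
    start = parts.mature_start
    interval = MatureInterval(start=start, end=start + mat_n, mature_id=f"{record_id}-5p")
    record = PreMiRNARecord(
        precursor=RNASequence(id=record_id, residues=precursor),
        matures=(interval,),
        label=label,
    )
    return (record, parts) if return_parts else record


def generate_dataset(config: SynthConfig) -> list[PreMiRNARecord]:
    """n_pos essential + n_neg non-essential records, reproducible per seed."""
    if config.n_pos < 1 or config.n_neg < 1:
        raise ValueError("n_pos and n_neg must be at least 1")
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_pos):
        records.append(generate_hairpin(rng, config, 1, f"syn-pos-{i:04d}"))
    for i in range(config.n_neg):
        records.append(generate_hairpin(rng, config, 0, f"syn-neg-{i:04d}"))
    return records


def write_dataset(records: Sequence[PreMiRNARecord], out_dir: str | Path) -> dict[str, Path]:
    """Emit precursors.fa / matures.fa / mapping.tsv in the benchmark dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "precursors": out_dir / "precursors.fa",
        "matures": out_dir / "matures.fa",
        "mapping": out_dir / "mapping.tsv",
    }
    precursors = [r.precursor for r in records]
    matures = [
        RNASequence(id=m.mature_id, residues=r.precursor.residues[m.start : m.end])
        for r in records
        for m in r.matures
    ]
    write_fasta(paths["precursors"], precursors)
    write_fasta(paths["matures"], matures)
    write_mapping(paths["mapping"], records)
    return paths
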