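"""RNA secondary-structure quantities behind a pluggable engine contract.

Hairpin-structure descriptors of the precursor (minimum free energy, base-pair
probabilities and the ensemble statistics dP/dQ/dD derived from them) can come
from two engines:

* ``ReferenceEngine`` — a built-in maximum base-pairing model: Nussinov-style
  dynamic programming for the "MFE" structure (energy is the dimensionless
  pseudo-energy −pair_count, NOT kcal/mol) and a McCaskill-style inside/outside
  recursion over the same structure space for base-pair probabilities, with a
  Boltzmann weight ``pair_weight`` per base pair.  Fully deterministic, no
  external dependency; this is what the tests and default pipeline use.
* ``ViennaEngine`` — an adapter over the ViennaRNA (RNAlib) python bindings,
  giving thermodynamic MFE structures in kcal/mol and equilibrium base-pair
  probabilities.  Selected with ``get_engine("vienna")`` when the bindings are
  installed.

Both engines expose ``fold(seq) -> MFEResult`` and
``pair_probabilities(seq) -> BasePairProbMatrix``; downstream feature code is
engine-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seq_io import RNASequence

__all__ = [
    "MFEResult",
    "BasePairProbMatrix",
    "FoldMetrics",
    "CANONICAL_PAIRS",
    "reference_nussinov",
    "reference_partition",
    "structure_metrics",
    "fold_mfe",
    "compute_fold_metrics",
    "ReferenceEngine",
    "ViennaEngine",
    "get_engine",
]

#: Watson-Crick plus GU wobble pairs.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Minimum number of unpaired nucleotides enclosed by a hairpin-closing pair.
DEFAULT_MIN_LOOP = 3

#: Default Boltzmann weight per base pair in the reference partition function.
DEFAULT_PAIR_WEIGHT = math.e


@dataclass(frozen=True)
class MFEResult:
    structure: str  # dot-bracket, same length as the sequence
    energy: float  # kcal/mol (external engine) or -pair_count (reference)
    pair_count: int

    def __post_init__(self):
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced dot-bracket structure")
        if self.pair_count != self.structure.count("("):
            raise ValueError("pair_count inconsistent with dot-bracket string")


@dataclass(frozen=True)
class BasePairProbMatrix:
    """Symmetric L×L matrix of base-pair probabilities p_ij."""

    p: np.ndarray

    def __post_init__(self):
        p = self.p
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("probability matrix must be square")
        if not np.allclose(p, p.T, atol=1e-9):
            raise ValueError("probability matrix must be symmetric")
        if p.min() < -1e-12 or p.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        rowsum = p.sum(axis=1)
        if rowsum.max() > 1 + 1e-6:
            raise ValueError("a position pairs with total probability > 1")


@dataclass(frozen=True)
class FoldMetrics:
    """Ensemble/structure descriptors of one precursor (see module docstring)."""

    mfe: float
    nmfe: float
    dP: float
    dP_L: float
    dQ: float
    dQ_L: float
    dD: float
    dD_L: float


def _pairable_matrix(residues: str, min_loop: int, allowed_pairs) -> np.ndarray:
    n = len(residues)
    ok = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if (residues[i], residues[j]) in allowed_pairs:
                ok[i, j] = True
    return ok


def reference_nussinov(
    seq: RNASequence | str,
    min_loop: int = DEFAULT_MIN_LOOP,
    allowed_pairs=CANONICAL_PAIRS,
) -> MFEResult:
    """Maximum base-pairing structure via Nussinov dynamic programming.

    Energy is the pseudo-energy −(number of pairs).  Traceback is
    deterministic: at each subproblem a pairing of the left end is preferred
    over leaving it unpaired, and among optimal partners the smallest index
    is taken.
    """
    residues = seq.residues if isinstance(seq, RNASequence) else seq
    n = len(residues)
    if n < 1:
        raise ValueError("empty sequence")
    ok = _pairable_matrix(residues, min_loop, allowed_pairs)
    N = np.zeros((n + 1, n + 1), dtype=np.int64)  # N[i, j+1] = max pairs in s[i..j]

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j + 1]  # i unpaired
            ks = np.nonzero(ok[i, i : j + 1])[0] + i
            for k in ks:
                cand = 1 + N[i + 1, k] + N[k + 1, j + 1]
                if cand > best:
                    best = cand
            N[i, j + 1] = best

    structure = ["."] * n
    pairs = 0
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = N[i, j + 1]
        if target == 0:
            continue
        placed = False
        for k in range(i + min_loop + 1, j + 1):
            if ok[i, k] and 1 + N[i + 1, k] + N[k + 1, j + 1] == target:
                structure[i], structure[k] = "(", ")"
                pairs += 1
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                placed = True
                break
        if not placed:
            stack.append((i + 1, j))
    return MFEResult(structure="".join(structure), energy=-float(pairs), pair_count=pairs)


def _partition_linear(ok: np.ndarray, w: float) -> np.ndarray:
    """Inside/outside recursion in linear space.  Returns p_ij (upper triangle)."""
    n = ok.shape[0]
    # Z[a, b] = weighted structure count over the half-open region [a, b)
    Z = np.ones((n + 1, n + 1))
    for span in range(2, n + 1):
        for a in range(0, n - span + 1):
            b = a + span
            total = Z[a + 1, b]  # a unpaired
            ks = np.nonzero(ok[a, a:b])[0] + a
            if ks.size:
                total += w * np.dot(Z[a + 1, ks], Z[ks + 1, b])
            Z[a, b] = total

    # Outside: Zhat[i, j] sums structures of the complement of [i, j], split by
    # the innermost pair (h, l) enclosing (i, j) — or no enclosing pair at all.
    Zhat = np.zeros((n, n))
    p = np.zeros((n, n))
    Ztot = Z[0, n]
    ij_pairs = sorted(zip(*np.nonzero(ok)), key=lambda t: t[0] - t[1])  # span desc
    for i, j in ij_pairs:
        val = Z[0, i] * Z[j + 1, n]
        if i > 0 and j < n - 1:
            block = Zhat[:i, j + 1 :] * np.outer(Z[1 : i + 1, i], Z[j + 1, j + 1 : n])
            val += w * block.sum()
        Zhat[i, j] = val
        p[i, j] = w * Z[i + 1, j] * Zhat[i, j] / Ztot
    return p


def _partition_log(ok: np.ndarray, w: float) -> np.ndarray:
    """Same recursions in log space (guards overflow on long sequences)."""
    from scipy.special import logsumexp

    n = ok.shape[0]
    logw = math.log(w)
    NEG = -np.inf
    lZ = np.zeros((n + 1, n + 1))
    for span in range(2, n + 1):
        for a in range(0, n - span + 1):
            b = a + span
            terms = [lZ[a + 1, b]]
            ks = np.nonzero(ok[a, a:b])[0] + a
            if ks.size:
                terms.append(logsumexp(logw + lZ[a + 1, ks] + lZ[ks + 1, b]))
            lZ[a, b] = logsumexp(terms)

    lZhat = np.full((n, n), NEG)
    p = np.zeros((n, n))
    ij_pairs = sorted(zip(*np.nonzero(ok)), key=lambda t: t[0] - t[1])
    for i, j in ij_pairs:
        terms = [lZ[0, i] + lZ[j + 1, n]]
        if i > 0 and j < n - 1:
            block = (
                lZhat[:i, j + 1 :]
                + lZ[1 : i + 1, i][:, None]
                + lZ[j + 1, j + 1 : n][None, :]
            )
            finite = block[np.isfinite(block)]
            if finite.size:
                terms.append(logw + logsumexp(finite))
        lZhat[i, j] = logsumexp(terms)
        p[i, j] = math.exp(logw + lZ[i + 1, j] + lZhat[i, j] - lZ[0, n])
    return p


def reference_partition(
    seq: RNASequence | str,
    min_loop: int = DEFAULT_MIN_LOOP,
    pair_weight: float = DEFAULT_PAIR_WEIGHT,
    allowed_pairs=CANONICAL_PAIRS,
) -> BasePairProbMatrix:
    """Base-pair probabilities over the maximum-pairing structure space.

    Each structure gets Boltzmann weight ``pair_weight ** n_pairs``;
    p_ij is the weighted fraction of structures containing the pair (i, j).
    For |S| > 200 the recursion switches to log-space accumulation so the
    partition sums cannot overflow.
    """
    residues = seq.residues if isinstance(seq, RNASequence) else seq
    if pair_weight <= 0:
        raise ValueError("pair_weight must be positive")
    ok = _pairable_matrix(residues, min_loop, allowed_pairs)
    if len(residues) > 200:
        p = _partition_log(ok, pair_weight)
    else:
        p = _partition_linear(ok, pair_weight)
        if not np.all(np.isfinite(p)):
            p = _partition_log(ok, pair_weight)
    return BasePairProbMatrix(p=p + p.T)


def structure_metrics(
    seq: RNASequence | str,
    mfe: MFEResult,
    probs: BasePairProbMatrix,
) -> FoldMetrics:
    """Derive dP/dQ/dD (and their /L variants), MFE and nMFE.

    dP = pairs/L is the base-pairing propensity; dQ is the Shannon entropy of
    the pair-probability ensemble per length, −(1/L)·Σ_{i<j} p_ij·log2 p_ij;
    dD = (1/L)·Σ_{i<j} p_ij·(1−p_ij) is the expected base-pair distance to the
    ensemble (ensemble diversity) per length.
    """
    residues = seq.residues if isinstance(seq, RNASequence) else seq
    L = len(residues)
    if probs.p.shape[0] != L:
        raise ValueError("probability matrix dimension does not match sequence length")
    iu = np.triu_indices(L, k=1)
    pij = probs.p[iu]
    nz = pij > 0
    dQ = float(-(pij[nz] * np.log2(pij[nz])).sum() / L)
    dD = float((pij * (1.0 - pij)).sum() / L)
    dP = mfe.pair_count / L
    return FoldMetrics(
        mfe=mfe.energy,
        nmfe=mfe.energy / L,
        dP=dP,
        dP_L=dP / L,
        dQ=dQ,
        dQ_L=dQ / L,
        dD=dD,
        dD_L=dD / L,
    )


class EngineUnavailableError(RuntimeError):
    pass


class ReferenceEngine:
    """Built-in maximum-pairing engine (pseudo-energy units, no dependency)."""

    name = "reference"

    def __init__(
        self,
        min_loop: int = DEFAULT_MIN_LOOP,
        pair_weight: float = DEFAULT_PAIR_WEIGHT,
        allowed_pairs=CANONICAL_PAIRS,
    ):
        self.min_loop = min_loop
        self.pair_weight = pair_weight
        self.allowed_pairs = allowed_pairs

    def fold(self, seq: RNASequence | str) -> MFEResult:
        return reference_nussinov(seq, self.min_loop, self.allowed_pairs)

    def pair_probabilities(self, seq: RNASequence | str) -> BasePairProbMatrix:
        return reference_partition(seq, self.min_loop, self.pair_weight, self.allowed_pairs)


class ViennaEngine:
    """Adapter over the ViennaRNA (RNAlib) python bindings; energies in kcal/mol."""

    name = "vienna"

    def __init__(self):
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover - depends on install
            raise EngineUnavailableError(
                "ViennaRNA python bindings ('RNA') are not installed; "
                "use get_engine('reference') for the built-in engine"
            ) from exc
        self._RNA = RNA

    def fold(self, seq: RNASequence | str) -> MFEResult:
        residues = seq.residues if isinstance(seq, RNASequence) else seq
        ss, energy = self._RNA.fold(residues)
        return MFEResult(structure=ss, energy=float(energy), pair_count=ss.count("("))

    def pair_probabilities(self, seq: RNASequence | str) -> BasePairProbMatrix:
        residues = seq.residues if isinstance(seq, RNASequence) else seq
        fc = self._RNA.fold_compound(residues)
        fc.pf()
        raw = np.asarray(fc.bpp())  # (L+1)x(L+1), 1-based upper triangle
        p = raw[1:, 1:]
        p = np.triu(p, k=1)
        return BasePairProbMatrix(p=p + p.T)


def get_engine(name: str = "reference", **kwargs):
    if name == "reference":
        return ReferenceEngine(**kwargs)
    if name == "vienna":
        return ViennaEngine(**kwargs)
    raise ValueError(f"unknown structure engine {name!r} (choose 'reference' or 'vienna')")


def fold_mfe(seq: RNASequence | str, engine=None) -> MFEResult:
    """Fold with the given engine (default: the built-in reference engine)."""
    engine = engine or ReferenceEngine()
    return engine.fold(seq)


def compute_fold_metrics(seq: RNASequence | str, engine=None) -> FoldMetrics:
    """Convenience: fold + pair probabilities + metric derivation in one call."""
    engine = engine or ReferenceEngine()
    return structure_metrics(seq, engine.fold(seq), engine.pair_probabilities(seq))
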