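# Methods

## Problem and model

Some microRNAs are *essential*: knocking them out produces a strong organismal
phenotype. Given a precursor hairpin (pre-miRNA, ~60–120 nt) and the location
of its mature arm(s) (~22 nt), the package predicts a probability that the
miRNA is essential. The classifier fuses two views of the precursor:

**Handcrafted static feature F_s (38 dims).** U/C/G content fractions of the
precursor, the mature arm(s) and the non-mature remainder (3×3); total mature
length and non-mature length (2); a ternary cleavage-site class — 1 if the
5'-most nucleotide of every mature arm is U, −1 if none is, 0 otherwise (1);
overlapping dinucleotide counts over the 9 A-free pairs in the precursor and
in the mature arm(s) (2×9); MFE and MFE/L of the hairpin (2); and six
ensemble descriptors (dP, dP/L, dQ, dQ/L, dD, dD/L) from base-pair
probabilities: dP = pairs/L, dQ = −(1/L)·Σ_{i<j} p_ij log₂ p_ij,
dD = (1/L)·Σ_{i<j} p_ij(1−p_ij). A never appears in content/dinucleotide
numerators: with three of four base frequencies fixed the fourth is
redundant. Two-arm precursors use the concatenation of both arms for the
mature blocks (dimensionality stays fixed); the artificial junction
dinucleotide is not counted. F_s is z-scored per dimension with statistics
fit on training folds only; zero-variance dimensions pass through unchanged.

**Learned sequence feature.** The precursor is split into overlapping k-mers
(stride 1, default k = 4, vocabulary 4^k learned embeddings of width
d_b = 128). A BiLSTM encodes the token sequence; the per-position feature
F_B is the element-wise *sum* of the forward and backward hidden states.
Multi-head scaled dot-product self-attention (h = 4 heads, d_k = d_v = 64,
Q = K = V = F_B) is concatenated and projected to d_output = 38, giving F_M.
A weight-attention step fuses F_M with the static view:
h_m = ReLU(W_inter·F_s + b_inter), h_i = ReLU(w_conv·F_M,i + b_conv),
α_i = σ(h_mᵀh_i), F_W = Σ_i α_i·h_i over real (unmasked) positions. The α_i
are independent logistic gates per position, not a softmax across positions.
The final feature F_f = [F_s; F_W] (d_f = 76) feeds an MLP (one ReLU hidden
layer of width 76 by default) with a 2-way softmax head. Training minimizes
mean cross-entropy plus (λ/2)·Σ‖W‖² over weight matrices (biases excluded)
with Adam.

Architecture notes, where the published description is ambiguous or
self-inconsistent, resolved as follows:

- Tokens are embedded per k-mer (one learned vector per 4^k-word). Embedding
  each nucleotide and concatenating k of them cannot produce the stated
  width 128 for k = 3; a per-token table has equal capacity and consistent
  dimensions for every k.
- The two bias vectors of the weight-attention step (b_inter, b_conv) are
  independent parameters; tying them is recoverable but has no rationale.
- The softmax head and the cross-entropy are the standard definitions; the
  attention output width is asserted equal to the static width 38 at
  construction because the fusion inner product h_mᵀh_i requires it.
- MLP hidden layers use the standard f(Wh + b) form.
- Variable-length batching pads on the right with a dedicated token; padded
  positions are excluded from attention (−∞ logits on padded keys) and from
  the F_W sum. Appending padding changes no output beyond 1e-9 (tested).

## Structure engines

Structure descriptors come from a pluggable engine with two implementations.

*Reference engine (default, used by all tests):* maximum base-pairing
(Nussinov) dynamic programming over Watson–Crick + G·U wobble pairs with
minimum hairpin loop 3; the reported "energy" is the dimensionless
pseudo-energy −(pair count), not kcal/mol. Base-pair probabilities come from
a McCaskill-style inside/outside recursion over the same structure space,
each structure Boltzmann-weighted by pair_weight^(#pairs) (default e per
pair). Both recursions are exact for their model: on every sequence of
length ≤ 12 they reproduce exhaustive enumeration over all legal structures
to 1e-10 (tested on random sequences). The outside recursion conditions on
the innermost pair enclosing (i, j), which makes the decomposition
unambiguous; it is O(n⁴) with the inner double sum vectorized, ~0.1 s at
n = 110. Above 200 nt the recursions switch to log-space accumulation so
partition sums cannot overflow.

*Vienna engine (optional):* an adapter over the ViennaRNA (RNAlib) python
bindings giving thermodynamic MFE (kcal/mol) and equilibrium pair
probabilities. Feature code is engine-agnostic; swapping engines changes
values, never shapes or the /L relationships. Whether pair probabilities
should come from the full thermodynamic ensemble or a simplified one is
exposed rather than fixed: engine choice and pair_weight are configuration.

## Evaluation protocol

Stratified five-fold cross-validation. Folds are dealt round-robin per
class, carrying the dealing position across classes, so *total* fold sizes
differ by at most one as well as per-class counts (77+77 → sizes
31,31,31,31,30, positives 16,16,15,15,15). A generic per-class splitter
that always fills the earliest folds first violates this (32,32,30,30,30).
Standardizer statistics and all model parameters are re-fit per fold from
its training split; the k-mer vocabulary is the fixed enumeration of all
4^k words, so no test information can enter it. AUC is reported pooled
(one ranking over all out-of-fold scores — matching a single published ROC
curve) and as the per-fold mean; ACC and F1 threshold p₁ at 0.5 (no
threshold is prescribed by the source protocol; 0.5 is the symmetric
choice). AUC uses the rank method with ties counted 0.5, equal to the
normalized Mann–Whitney U (tested to 1e-12). Negative sampling from an
unlabeled pool is uniform without replacement, seeded.

## Synthetic data generator

The generator emulates the benchmark's data model so the whole pipeline is
testable offline: each record is flank–stem–loop–stem'–flank with the 3'
stem the exact reverse complement of the 5' stem (the reference engine then
finds ≥ 0.8·stem_len pairs), stem 18–30 nt, loop 4–10 nt, A-rich flanks
padding the total length into 60–120 nt, and one mature interval (20–24 nt)
on the 5' arm. Class signal enters through exactly two knobs, both visible
to the handcrafted extractor *and* the sequence encoder: stem GC probability
(essential 0.70 vs non-essential 0.45 under the "strong" preset) and the
probability that the mature arm starts with U (0.9 vs 0.3), driving the
cleavage-site class. The "weak" preset halves both gaps; "none" equalizes
the classes for null-behaviour checks. Class-conditional statistics converge
to the configured values (law-of-large-numbers test at n = 500, tolerance
0.05).

What the generator does **not** emulate: bulges and internal loops (stems
are perfectly complementary), sequence-family structure and homology between
records, miRBase-style 3p/5p arm pairs (one arm per record), and any
biological determinant of essentiality beyond the two planted statistics.
Passing the recovery tests therefore shows that the pipeline extracts and
classifies planted sequence/structure signal without leakage — not that the
model attains any particular accuracy on curated essentiality data.

## Configurations and numerical choices

`ModelConfig()` defaults follow the published setting: k = 4, d_b = 128,
d_k = d_v = 64, h = 4, hidden width 76, λ = 1e-4, Adam lr 1e-3, 200 epochs,
batch 16. The optimizer, epochs and batch size are not stated by the source
and are exposed configuration with these defaults.

`ModelConfig.compact()` is the package's desk-scale configuration, used by
the cross-validation demonstrations and the acceptance script: d_b = 16,
d_k = d_v = 8, h = 4, 15 epochs, batch 32, lr 3e-3, λ = 5e-2. The narrower
encoder and short schedule make a full 5×CV on a few hundred records run in
minutes on one CPU; the stronger L2 compensates for the small sample
(~160 training records per fold), where the from-scratch deep branch
otherwise overfits. The fusion projections (W_inter, w_conv) are initialized
at 0.3× Glorot scale in every configuration, so the classifier exploits the
standardized static features immediately and grows the learned-sequence
contribution as training warrants — the small-sample analogue of quiet
residual-branch initialization.

Other numerical choices: all arithmetic is float64; softmax and
log-sum-exp are max-shifted; sigmoid inputs are clipped at ±500; a
probability of exactly 0 at the true label in the reporting-level loss is
clamped at 1e-12 with a warning; Nussinov traceback prefers pairing the
left end and the smallest partner index, making structures deterministic;
gradients are produced by a small reverse-mode autodiff tape over NumPy
(package module `autodiff`) and verified end-to-end against central finite
differences at 1e-4 relative tolerance; Adam uses β = (0.9, 0.999),
ε = 1e-8. Every source of randomness (initialization, shuffling, fold
dealing, data generation) descends from explicit integer seeds; per-fold
training seeds are derived as seed + 101·(fold+1).

## Known limitations

- The reference engine's pseudo-energy is not comparable across engines in
  magnitude, only in sign and ordering; users wanting thermodynamic values
  must select the Vienna engine.
- Training is CPU-only and single-threaded; the full published
  configuration (d_b = 128, 200 epochs) is practical for one run but slow
  inside repeated cross-validation.
- Reproducing the published benchmark numbers requires the curated
  essentiality dataset and its specific negative sample, which are not
  redistributed here; see the README for the informational external check.
- With only ~150 training records per fold the deep branch is strongly
  regularized; on much larger corpora the compact configuration will
  under-fit and the full configuration should be preferred.
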