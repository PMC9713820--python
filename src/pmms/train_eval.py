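"""Training loop, stratified five-fold cross-validation and metrics.

The evaluation protocol: samples are split into five stratified folds of
near-equal size (sizes differ by at most one in total AND per class); each
fold serves once as the test set while the rest train the model.  Feature
standardization is fit on the training folds only.  AUC is reported both
pooled (one ranking over all out-of-fold scores) and as the per-fold mean;
ACC and F1 use a 0.5 threshold on the essentiality probability.

Note on fold construction: a generic per-class splitter that gives every
class's larger folds to the earliest folds can make total fold sizes differ
by two (e.g. 77+77 → 32,32,30,30,30).  ``make_folds`` instead deals each
class round-robin, continuing the dealing position across classes, so totals
stay within one (77+77 → 31,31,31,31,30 with positives 16,16,15,15,15).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .model import (
    ModelConfig,
    ModelParameters,
    batch_loss_t,
    encode_tokens,
    forward_batch,
    init_parameters,
    predict_proba,
)
from .seq_io import PreMiRNARecord, tokenize_kmers
from .static_features import (
    FEATURE_NAMES,
    StandardizerStats,
    apply_standardizer,
    feature_matrix,
    fit_standardizer,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "EvalReport",
    "sample_negatives",
    "make_folds",
    "train",
    "evaluate",
    "compute_metrics",
    "cross_validate",
    "export_final_features",
    "write_feature_tsv",
]


@dataclass(frozen=True)
class FoldPlan:
    """Stratified assignment of record ids to folds."""

    assignments: dict[str, int]
    n_folds: int
    seed: int

    def fold_indices(self, records: Sequence[PreMiRNARecord], fold: int):
        test = [i for i, r in enumerate(records) if self.assignments[r.precursor.id] == fold]
        train = [i for i, r in enumerate(records) if self.assignments[r.precursor.id] != fold]
        return train, test


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation metrics with full provenance."""

    per_fold: list[dict]
    pooled_auc: float
    mean_auc: float
    mean_acc: float
    mean_f1: float
    threshold: float
    seed: int
    n_folds: int
    config: dict
    fold_assignments: dict[str, int]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


def sample_negatives(
    pool: Sequence[PreMiRNARecord], n: int, seed: int
) -> list[PreMiRNARecord]:
    """Uniform sample without replacement from the unlabeled/negative pool."""
    if n > len(pool):
        raise ValueError(f"cannot sample {n} records from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pool))[:n]
    return [pool[i] for i in idx]


def make_folds(
    dataset: Sequence[PreMiRNARecord], n_folds: int = 5, seed: int = 0
) -> FoldPlan:
    """Stratified folds; total and per-class fold sizes differ by at most 1."""
    labels = [r.label for r in dataset]
    if any(l is None for l in labels):
        raise ValueError("all records must be labeled for fold construction")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    offset = 0  # rolling dealing position, carried across classes
    for cls in sorted(set(labels)):
        members = [i for i, l in enumerate(labels) if l == cls]
        if len(members) < n_folds:
            raise ValueError(
                f"class {cls} has {len(members)} members; needs at least {n_folds}"
            )
        members = [members[i] for i in rng.permutation(len(members))]
        for j, idx in enumerate(members):
            assignments[dataset[idx].precursor.id] = (offset + j) % n_folds
        offset = (offset + len(members)) % n_folds
    return FoldPlan(assignments=assignments, n_folds=n_folds, seed=seed)


def _adam_step(params: ModelParameters, state: dict, lr: float, t: int) -> None:
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for name, tensor in params.trainable():
        if tensor.grad is None:
            continue
        m, v = state.setdefault(name, (np.zeros_like(tensor.data), np.zeros_like(tensor.data)))
        m = beta1 * m + (1 - beta1) * tensor.grad
        v = beta2 * v + (1 - beta2) * tensor.grad**2
        state[name] = (m, v)
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        tensor.data -= lr * mhat / (np.sqrt(vhat) + eps)
        tensor.grad = None


def train(
    train_records: Sequence[PreMiRNARecord],
    static_matrix: np.ndarray,
    config: ModelConfig,
) -> ModelParameters:
    """Minibatch Adam on cross-entropy + L2; deterministic given config.seed.

    ``static_matrix`` holds the already-standardized F_s row per record
    (standardizer fit on these training records only, by the caller).
    """
    labels = np.array([r.label for r in train_records], dtype=np.int64)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both classes present")
    static_matrix = np.asarray(static_matrix, dtype=np.float64)
    if static_matrix.shape != (len(train_records), 38):
        raise ValueError("static_matrix must be (n_records, 38)")

    params = init_parameters(config)
    token_seqs = [tokenize_kmers(r.precursor, config.k) for r in train_records]
    rng = np.random.default_rng((config.seed + 1) % 2**31)
    adam_state: dict = {}
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_records))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            ids, mask = encode_tokens([token_seqs[i] for i in batch], params)
            _, z = forward_batch(params, ids, mask, static_matrix[batch])
            L = batch_loss_t(z, labels[batch], params, config.lambda_l2)
            if not np.isfinite(L.data):
                raise RuntimeError(
                    f"training diverged (loss={L.data!r}) at epoch {epoch}, "
                    f"step {step}; lower the learning rate"
                )
            L.backward()
            step += 1
            _adam_step(params, adam_state, config.learning_rate, step)
            epoch_loss += float(L.data) * len(batch)
        params.loss_history.append(epoch_loss / len(order))
        logger.debug("epoch %d: mean loss %.5f", epoch, params.loss_history[-1])
    return params


def evaluate(
    params: ModelParameters,
    test_records: Sequence[PreMiRNARecord],
    static_matrix: np.ndarray,
    batch_size: int = 32,
) -> np.ndarray:
    """Essentiality probability p_1 per record (standardized features in)."""
    static_matrix = np.asarray(static_matrix, dtype=np.float64)
    token_seqs = [tokenize_kmers(r.precursor, params.config.k) for r in test_records]
    scores = np.empty(len(test_records))
    for start in range(0, len(test_records), batch_size):
        sl = slice(start, start + batch_size)
        ids, mask = encode_tokens(token_seqs[sl], params)
        _, z = forward_batch(params, ids, mask, static_matrix[sl])
        scores[sl] = predict_proba(z.data)[:, 1]
    return scores


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(AUC, ACC, F1).  AUC is rank-based with ties at 0.5 (Mann–Whitney);
    single-class label sets make it undefined (NaN)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(set(labels.tolist())) < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
    pred = (scores >= threshold).astype(np.int64)
    acc = float(accuracy_score(labels, pred))
    f1 = float(f1_score(labels, pred, zero_division=0))
    return auc, acc, f1


def cross_validate(
    dataset: Sequence[PreMiRNARecord],
    config: ModelConfig,
    n_folds: int = 5,
    engine=None,
    threshold: float = 0.5,
    features: np.ndarray | None = None,
) -> EvalReport:
    """Stratified k-fold CV with fold-local standardization and training.

    Structure features are per-record quantities (no cross-record information),
    so they are computed once up front; standardizer statistics and all model
    parameters are re-fit inside each fold from its training split only.
    """
    if features is None:
        features = feature_matrix(dataset, engine)
    labels = np.array([r.label for r in dataset], dtype=np.int64)
    plan = make_folds(dataset, n_folds=n_folds, seed=config.seed)

    per_fold = []
    pooled_scores = np.empty(len(dataset))
    pooled_mask = np.zeros(len(dataset), dtype=bool)
    for fold in range(n_folds):
        tr, te = plan.fold_indices(dataset, fold)
        stats = fit_standardizer(features[tr])
        Xtr = np.vstack([apply_standardizer(features[i], stats) for i in tr])
        Xte = np.vstack([apply_standardizer(features[i], stats) for i in te])
        fold_config = replace(config, seed=(config.seed + 101 * (fold + 1)) % 2**31)
        params = train([dataset[i] for i in tr], Xtr, fold_config)
        scores = evaluate(params, [dataset[i] for i in te], Xte)
        pooled_scores[te] = scores
        pooled_mask[te] = True
        auc, acc, f1 = compute_metrics(scores, labels[te], threshold)
        per_fold.append(
            {"fold": fold, "auc": auc, "acc": acc, "f1": f1, "n_test": len(te)}
        )
        logger.info("fold %d: AUC %.4f ACC %.4f F1 %.4f (n=%d)", fold, auc, acc, f1, len(te))
    assert pooled_mask.all(), "every record must be scored exactly once"

    pooled_auc, _, _ = compute_metrics(pooled_scores, labels, threshold)
    return EvalReport(
        per_fold=per_fold,
        pooled_auc=pooled_auc,
        mean_auc=float(np.mean([f["auc"] for f in per_fold])),
        mean_acc=float(np.mean([f["acc"] for f in per_fold])),
        mean_f1=float(np.mean([f["f1"] for f in per_fold])),
        threshold=threshold,
        seed=config.seed,
        n_folds=n_folds,
        config=config.to_dict(),
        fold_assignments=dict(plan.assignments),
    )


def export_final_features(
    params: ModelParameters,
    records: Sequence[PreMiRNARecord],
    stats: StandardizerStats,
    features: np.ndarray | None = None,
    engine=None,
) -> tuple[list[str], np.ndarray]:
    """Fused F_f vectors (76-dim) per record, for external 2-D projections."""
    if features is None:
        features = feature_matrix(records, engine)
    X = np.vstack([apply_standardizer(f, stats) for f in features])
    token_seqs = [tokenize_kmers(r.precursor, params.config.k) for r in records]
    out = np.empty((len(records), params.config.d_f))
    for start in range(0, len(records), 32):
        sl = slice(start, start + 32)
        ids, mask = encode_tokens(token_seqs[sl], params)
        F_f, _ = forward_batch(params, ids, mask, X[sl])
        out[sl] = F_f.data
    return [r.precursor.id for r in records], out


def write_feature_tsv(
    path: str | Path,
    ids: Sequence[str],
    matrix: np.ndarray,
    names: Sequence[str] = FEATURE_NAMES,
) -> None:
    matrix = np.asarray(matrix)
    if matrix.shape[1] != len(names):
        names = [f"f{i}" for i in range(matrix.shape[1])]
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(names) + "\n")
        for rid, row in zip(ids, matrix):
            fh.write(rid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")
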