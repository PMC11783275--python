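"""Dataset assembly, MSE/Adam training, and homology-aware cross-validation.

Training minimizes the mean squared error between predicted and
experimental ddG with the Adam optimizer on minibatches (default size
128), for up to 500 epochs with early stopping: a protein-grouped
validation subset is carved from the training data and the parameters from
the epoch with minimum validation MSE are returned.

Two protocol elements matter scientifically:

* **Reversibility augmentation** — thermodynamic reversibility,
  ddG(A->B) = -ddG(B->A), lets the training set be doubled by adding, for
  every variation, the reverse variation (variant sequence as wild type,
  swapped substitution, negated target). This balances the bias toward
  destabilizing measurements and teaches the model antisymmetry.
* **Homology-aware folds** — proteins sharing > 25% pairwise sequence
  identity are confined to the same cross-validation subset (single-
  linkage clusters are atomic), and all variations of a protein stay
  together, so no homology leaks between training and evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from . import metrics as _metrics
from .embedding import Embedder, difference_encoding
from .model import (
    ModelConfig,
    ModelParams,
    backward_batch,
    forward_batch,
    im2col,
)
from .sequences import (
    ProteinSequence,
    VariantSpec,
    apply_variants,
    parse_variant,
    read_fasta,
    read_variant_table,
)

DIRECT = "direct"
REVERSE = "reverse"


class TrainingDiverged(RuntimeError):
    """Non-finite loss encountered; carries the epoch it happened at."""

    def __init__(self, epoch: int, kind: str):
        super().__init__(f"non-finite {kind} loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class VariantRecord:
    """One labeled variation: protein, substitutions, target ddG, direction."""

    protein_id: str
    spec: VariantSpec
    y: Optional[float]
    direction: str = DIRECT

    def __post_init__(self) -> None:
        if self.direction not in (DIRECT, REVERSE):
            raise ValueError(f"direction must be direct|reverse, got {self.direction!r}")


@dataclass
class LabeledDataset:
    """Variant records together with the wild-type sequences they live on.

    For a reverse record the effective wild type is the mutated sequence;
    it is reconstructed on demand from the stored protein and the inverted
    spec, so only original sequences are kept.
    """

    proteins: dict[str, ProteinSequence]
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.protein_id not in self.proteins:
                raise ValueError(f"record references unknown protein {rec.protein_id!r}")
            apply_variants(self.wild_type_of(rec), rec.spec)  # applicability check

    def __len__(self) -> int:
        return len(self.records)

    def wild_type_of(self, rec: VariantRecord) -> ProteinSequence:
        base = self.proteins[rec.protein_id]
        if rec.direction == DIRECT:
            return base
        return apply_variants(base, rec.spec.inverted())

    def subset(self, protein_ids: Iterable[str]) -> "LabeledDataset":
        wanted = set(protein_ids)
        return LabeledDataset(
            proteins={p: s for p, s in self.proteins.items() if p in wanted},
            records=[r for r in self.records if r.protein_id in wanted],
        )


def load_dataset(fasta_path, tsv_path) -> LabeledDataset:
    """Assemble a dataset from a FASTA file and a variant TSV."""
    proteins = read_fasta(fasta_path)
    table = read_variant_table(tsv_path)
    records = []
    for row in table.itertuples(index=False):
        y = float(row.ddg) if "ddg" in table.columns else None
        direction = getattr(row, "direction", DIRECT)
        records.append(VariantRecord(row.protein_id, parse_variant(row.variant),
                                     y, direction))
    return LabeledDataset(proteins=proteins, records=records)


def augment_reverse(ds: LabeledDataset) -> LabeledDataset:
    """Double the dataset with reverse variations (negated targets).

    Augmenting an already-augmented set would double-count and is an error.
    """
    if any(r.direction == REVERSE for r in ds.records):
        raise ValueError("dataset already contains reverse records; "
                         "augment_reverse expects direct records only")
    added = [
        VariantRecord(
            r.protein_id,
            r.spec.inverted(),
            None if r.y is None else -r.y,
            REVERSE,
        )
        for r in ds.records
    ]
    return LabeledDataset(proteins=dict(ds.proteins), records=ds.records + added)


def mse_loss(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Mean squared error over a non-empty pair of equal-length vectors."""
    return _metrics.mse(y, y_hat)


# ---------------------------------------------------------------------------
# encoding records into padded batch tensors
# ---------------------------------------------------------------------------

def encode_records(
    ds: LabeledDataset, records: Sequence[VariantRecord], embedder: Embedder
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Difference-encode records into (N, Lmax, d) + mask + targets.

    Embeddings of repeated sequences are computed once (in-memory cache);
    padded rows of D are zero, so the convolution sees them exactly as the
    zero same-padding beyond the true sequence end.
    """
    cache: dict[str, np.ndarray] = {}

    def emb(seq: ProteinSequence) -> np.ndarray:
        matrix = cache.get(seq.residues)
        if matrix is None:
            matrix = embedder.embed(seq)
            cache[seq.residues] = matrix
        return matrix

    diffs = []
    for rec in records:
        wt = ds.wild_type_of(rec)
        vt = apply_variants(wt, rec.spec)
        diffs.append(difference_encoding(emb(wt), emb(vt)))
    n = len(diffs)
    lmax = max(D.shape[0] for D in diffs)
    X = np.zeros((n, lmax, embedder.d))
    mask = np.zeros((n, lmax), dtype=bool)
    for i, D in enumerate(diffs):
        X[i, : D.shape[0]] = D
        mask[i, : D.shape[0]] = True
    y = np.array([np.nan if r.y is None else r.y for r in records], dtype=np.float64)
    return X, mask, y


def predict_records(
    ds: LabeledDataset,
    records: Sequence[VariantRecord],
    embedder: Embedder,
    params: ModelParams,
    cfg: ModelConfig,
    batch_size: int = 128,
) -> np.ndarray:
    """Model predictions for a sequence of records, in order."""
    X, mask, _ = encode_records(ds, records, embedder)
    out = np.empty(len(records))
    for start in range(0, len(records), batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = forward_batch(X[sl], mask[sl], params, cfg)
    return out


# ---------------------------------------------------------------------------
# Adam + training loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam on MSE, early stopping on validation MSE)."""

    batch_size: int = 128
    max_epochs: int = 500
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    #: decoupled L2 weight decay (AdamW convention); 0 disables. Applied to
    #: weight matrices only, never to biases.
    weight_decay: float = 0.0
    #: multiplier on the initialization scale of all weight matrices.
    init_scale: float = 1.0
    #: reduce-on-plateau: multiply the learning rate by ``lr_decay_factor``
    #: whenever validation MSE has not improved for ``lr_decay_patience``
    #: consecutive epochs (factor 1.0 disables decay).
    lr_decay_factor: float = 1.0
    lr_decay_patience: int = 10

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.patience) < 1:
            raise ValueError("batch_size, max_epochs, patience must be positive")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.init_scale <= 0:
            raise ValueError("init_scale must be positive")
        if not (0.0 < self.lr_decay_factor <= 1.0) or self.lr_decay_patience < 1:
            raise ValueError("invalid learning-rate decay settings")


_BIAS_PARAMS = frozenset({"bc", "b1", "b2", "bO"})


class Adam:
    """Adam with bias correction and optional decoupled weight decay."""

    def __init__(self, params: ModelParams, cfg: TrainConfig):
        self.cfg = cfg
        self.lr = cfg.lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.as_dict().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.as_dict().items()}

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            update = (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + c.eps)
            target = getattr(params, k)
            if c.weight_decay > 0.0 and k not in _BIAS_PARAMS:
                update = update + c.weight_decay * target
            target[...] -= self.lr * update


@dataclass
class TrainResult:
    params: ModelParams
    cfg: ModelConfig
    log: list[dict]              # per-epoch {"epoch", "train_mse", "val_mse"}
    best_epoch: int
    best_val_mse: float
    val_proteins: list[str]


def _split_validation_proteins(
    records: Sequence[VariantRecord], val_fraction: float, rng: np.random.Generator
) -> list[str]:
    proteins = sorted({r.protein_id for r in records})
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins to carve a validation subset")
    n_val = max(1, math.ceil(val_fraction * len(proteins)))
    if n_val >= len(proteins):
        n_val = len(proteins) - 1
    order = rng.permutation(len(proteins))
    return [proteins[i] for i in order[:n_val]]


#: Precomputed conv windows are kept for the whole training set when they
#: fit in this many bytes; beyond it they are rebuilt per minibatch.
_WIN_CACHE_BYTES = 2 * 1024**3


def _maybe_im2col(X: np.ndarray, w: int) -> Optional[np.ndarray]:
    if X.shape[0] * X.shape[1] * w * X.shape[2] * 8 > _WIN_CACHE_BYTES:
        return None
    return im2col(X, w)


def _batched_mse(X, mask, y, params, cfg, batch_size, win=None) -> float:
    total = 0.0
    for start in range(0, X.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        y_hat = forward_batch(X[sl], mask[sl], params, cfg,
                              win=None if win is None else win[sl])
        total += float(np.sum((y_hat - y[sl]) ** 2))
    return total / X.shape[0]


def train(
    ds: LabeledDataset,
    embedder: Embedder,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    init_params: Optional[ModelParams] = None,
) -> TrainResult:
    """Fit the prediction head on a labeled dataset.

    A validation subset (grouped by protein, ``val_fraction`` of proteins,
    seeded) is held out for early stopping; the returned parameters are
    those of the epoch with minimum validation MSE. Fully reproducible for
    a fixed seed: data split, initialization, and minibatch order all
    derive from ``train_cfg.seed``.
    """
    if not ds.records:
        raise ValueError("empty dataset")
    if any(r.y is None for r in ds.records):
        raise ValueError("training requires a target ddG on every record")
    rng = np.random.default_rng(train_cfg.seed)

    val_proteins = _split_validation_proteins(ds.records, train_cfg.val_fraction, rng)
    val_set = set(val_proteins)
    train_recs = [r for r in ds.records if r.protein_id not in val_set]
    val_recs = [r for r in ds.records if r.protein_id in val_set]
    if not train_recs or not val_recs:
        raise ValueError("degenerate train/validation split")

    Xt, mt, yt = encode_records(ds, train_recs, embedder)
    Xv, mv, yv = encode_records(ds, val_recs, embedder)
    wt_all = _maybe_im2col(Xt, model_cfg.w)
    wv_all = _maybe_im2col(Xv, model_cfg.w)

    params = (init_params
              or ModelParams.init(model_cfg, embedder.d, rng,
                                  scale=train_cfg.init_scale)).copy()
    params.check_shapes(model_cfg)
    opt = Adam(params, train_cfg)

    log: list[dict] = []
    best_val = np.inf
    best_epoch = -1
    best_params = params.copy()
    stale = 0
    n_train = Xt.shape[0]
    for epoch in range(1, train_cfg.max_epochs + 1):
        order = rng.permutation(n_train)
        sq_sum = 0.0
        for start in range(0, n_train, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            y_hat, cache = forward_batch(
                Xt[idx], mt[idx], params, model_cfg, return_cache=True,
                win=None if wt_all is None else wt_all[idx],
            )
            resid = y_hat - yt[idx]
            sq_sum += float(np.sum(resid**2))
            dy = 2.0 * resid / idx.shape[0]
            grads = backward_batch(dy, cache, params)
            opt.step(params, grads)
        train_mse = sq_sum / n_train
        if not np.isfinite(train_mse):
            raise TrainingDiverged(epoch, "training")
        val_mse = _batched_mse(Xv, mv, yv, params, model_cfg,
                               train_cfg.batch_size, win=wv_all)
        if not np.isfinite(val_mse):
            raise TrainingDiverged(epoch, "validation")
        log.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val_mse,
                    "lr": opt.lr})
        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            best_params = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= train_cfg.patience:
                break
            if (train_cfg.lr_decay_factor < 1.0
                    and stale % train_cfg.lr_decay_patience == 0):
                opt.lr *= train_cfg.lr_decay_factor
    return TrainResult(
        params=best_params, cfg=model_cfg, log=log,
        best_epoch=best_epoch, best_val_mse=float(best_val),
        val_proteins=val_proteins,
    )


# ---------------------------------------------------------------------------
# sequence identity + homology-aware folds
# ---------------------------------------------------------------------------

#: Global (Needleman-Wunsch) alignment scoring used for identity: match +1,
#: mismatch 0, gap open -2, gap extend -0.5. Identity is the fraction of
#: identical aligned pairs over the alignment length (gaps included).
_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=0.0,
    open_gap_score=-2.0,
    extend_gap_score=-0.5,
)


def pairwise_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Global-alignment sequence identity in [0, 1]; symmetric; 1 for a == b."""
    if a.residues == b.residues:
        return 1.0
    aln = _ALIGNER.align(a.residues, b.residues)[0]
    counts = aln.counts()
    return counts.identities / aln.length


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping protein id -> fold index in 1..k."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, protein_id: str) -> int:
        return self.assignment[protein_id]

    def proteins_in(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.assignment.items()), columns=["protein_id", "fold"]
        )


def identity_matrix(seqs: Sequence[ProteinSequence]) -> np.ndarray:
    """Symmetric pairwise identity matrix (diagonal 1)."""
    n = len(seqs)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(seqs[i], seqs[j])
    return ident


def homology_folds(
    seqs: Sequence[ProteinSequence],
    k: int,
    threshold: float = 0.25,
    counts: Optional[dict[str, int]] = None,
    seed: int = 0,
) -> FoldAssignment:
    """Partition proteins into k folds with no cross-fold homology.

    Single-linkage clusters at ``threshold`` (transitive closure of
    pairwise identity > threshold) are atomic and are dealt greedily —
    largest variation count first, onto the currently lightest fold — to
    balance fold sizes. The no-leak constraint is re-checked exhaustively
    post hoc. Ties among equal-sized clusters are broken by the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    counts = counts or {pid: 1 for pid in ids}
    ident = identity_matrix(seqs)
    adjacency = csr_matrix(ident > threshold)
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp < k:
        raise ValueError(
            f"only {n_comp} single-linkage clusters at identity > {threshold}: "
            f"cannot form {k} folds without homology leakage"
        )
    clusters = [
        [ids[i] for i in range(len(ids)) if labels[i] == c] for c in range(n_comp)
    ]
    cluster_counts = [sum(counts.get(p, 0) for p in cl) for cl in clusters]
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n_comp))          # seeded tie-breaking …
    order.sort(key=lambda c: -cluster_counts[c])   # … under a stable size sort
    loads = [0] * k
    assignment: dict[str, int] = {}
    for c in order:
        fold = int(np.argmin(loads))
        loads[fold] += cluster_counts[c]
        for pid in clusters[c]:
            assignment[pid] = fold + 1

    # exhaustive post-hoc leak check
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if assignment[ids[i]] != assignment[ids[j]] and ident[i, j] > threshold:
                raise AssertionError(
                    f"cross-fold identity {ident[i, j]:.2f} > {threshold} "
                    f"between {ids[i]} and {ids[j]}"
                )
    return FoldAssignment(assignment=assignment, k=k)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list[_metrics.MetricsReport]
    fold_train_results: list[Optional[TrainResult]]
    summary: dict[str, tuple[float, float]]   # metric -> (mean, std over folds)

    def format_summary(self) -> str:
        return "  ".join(
            f"{name}={mean:.2f}±{std:.2f}" for name, (mean, std) in self.summary.items()
        )


PredictFn = Callable[[LabeledDataset, VariantRecord], float]


def cross_validate(
    ds: LabeledDataset,
    embedder: Embedder,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    folds: FoldAssignment,
    predict_fn: Optional[PredictFn] = None,
) -> CVResult:
    """Protein-grouped k-fold cross-validation with reversibility augmentation.

    For each fold, a model is trained from scratch on the remaining folds
    (training records doubled with reverse variations) and scored on the
    held-out fold: the held-out direct records plus their induced reverse
    variations, so each fold report carries the full Total/Direct/Reverse
    and symmetry statistics. The summary aggregates the Total block as
    mean +/- standard deviation across folds.

    ``predict_fn`` replaces the trained model with an arbitrary per-record
    predictor (used to validate the metric plumbing with known oracles).
    """
    missing = {r.protein_id for r in ds.records} - set(folds.assignment)
    if missing:
        raise ValueError(f"fold assignment lacks protein(s) {sorted(missing)}")
    if any(r.direction == REVERSE for r in ds.records):
        raise ValueError("cross_validate expects a direct-only dataset")

    reports: list[_metrics.MetricsReport] = []
    train_results: list[Optional[TrainResult]] = []
    for fold in range(1, folds.k + 1):
        held = set(folds.proteins_in(fold))
        test_recs = [r for r in ds.records if r.protein_id in held]
        train_ds = ds.subset(p for p in ds.proteins if p not in held)
        if not test_recs or not train_ds.records:
            raise ValueError(f"fold {fold} leaves an empty train or test split")
        assert not any(r.protein_id in held for r in train_ds.records)

        rev_recs = [
            VariantRecord(r.protein_id, r.spec.inverted(),
                          None if r.y is None else -r.y, REVERSE)
            for r in test_recs
        ]
        if predict_fn is not None:
            p_dir = np.array([predict_fn(ds, r) for r in test_recs])
            p_inv = np.array([predict_fn(ds, r) for r in rev_recs])
            train_results.append(None)
        else:
            result = train(augment_reverse(train_ds), embedder, model_cfg, train_cfg)
            train_results.append(result)
            p_dir = predict_records(ds, test_recs, embedder, result.params,
                                    model_cfg, train_cfg.batch_size)
            p_inv = predict_records(ds, rev_recs, embedder, result.params,
                                    model_cfg, train_cfg.batch_size)
        e_dir = np.array([r.y for r in test_recs], dtype=np.float64)
        reports.append(_metrics.evaluate(e_dir, p_dir, p_inv))

    summary = {}
    for name in ("pcc", "rmse", "mae"):
        values = [getattr(rep.total, name) for rep in reports]
        if any(v is None for v in values):
            continue
        arr = np.array(values, dtype=np.float64)
        summary[name] = (float(arr.mean()), float(arr.std(ddof=0)))
    return CVResult(fold_reports=reports, fold_train_results=train_results,
                    summary=summary)
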