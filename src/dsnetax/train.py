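"""Training loop, top-k evaluation, long-tail head/tail reporting and the
ablation harness.

Evaluation follows the conventions of long-tailed classification: top-k
accuracy (is the true species among the k best-scoring predictions?) both
overall and on HEAD/TAIL partitions of the test set, where HEAD at
cutpoint c holds the records of species with >= c training reads and TAIL
the rest.  Genus-level accuracy is derived by mapping each predicted
species to its genus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import SpeciesClassifier, predict_topk
from .nn import Tensor, no_grad, softmax_cross_entropy
from .nn.optim import Adam, SGD
from .silva import Dataset


@dataclass
class TrainConfig:
    """Optimization settings; the architecture lives in DSNetaxConfig."""

    epochs: int = 60
    batch: int = 32
    lr: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    training_fraction: float = 1.0
    stop_at_val_top1: float | None = None  # early exit once reached (accuracy in %)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.training_fraction <= 1:
            raise ValueError("training_fraction must lie in (0, 1]")


@dataclass
class EmbeddedSet:
    """Embeddings stacked for training: X (N, 1, L', d), integer labels y."""

    X: np.ndarray
    y: np.ndarray
    species: list[str]          # per-record species name
    species_names: list[str]    # label id -> name
    genus_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.ndim == 3:
            self.X = self.X[:, None, :, :]
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")

    def __len__(self) -> int:
        return len(self.y)


def stack_embeddings(mats: Sequence[np.ndarray], labels: Sequence[int],
                     species: Sequence[str], species_names: Sequence[str],
                     genus_of: dict[str, str] | None = None) -> EmbeddedSet:
    L = max(m.shape[0] for m in mats)
    d = mats[0].shape[1]
    X = np.zeros((len(mats), 1, L, d), dtype=np.float64)
    for i, m in enumerate(mats):
        X[i, 0, :m.shape[0]] = m  # zero-pad shorter streams at the bottom
    return EmbeddedSet(X, np.asarray(labels, dtype=np.int64), list(species),
                       list(species_names), dict(genus_of or {}))


@dataclass
class EvalReport:
    topk_accuracy: dict[int, float]            # percent, per k
    genus_topk_accuracy: dict[int, float | None]
    n_records: int
    per_record_hits: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        ks = sorted(self.topk_accuracy)
        for a, b in zip(ks, ks[1:]):
            if self.topk_accuracy[a] > self.topk_accuracy[b] + 1e-9:
                raise ValueError("top-k accuracy must be nondecreasing in k")


@dataclass
class HeadTailReport:
    """Per-cutpoint HEAD/TAIL accuracies; empty parts are marked, not zeroed."""

    cutpoints: list[int]
    parts: dict[tuple[int, str], dict]  # (cutpoint, "head"|"tail") -> stats or {"empty": True}


def _logits_in_batches(model: SpeciesClassifier, X: np.ndarray,
                       batch: int = 64) -> np.ndarray:
    model.eval()
    outs = []
    with no_grad():
        for lo in range(0, len(X), batch):
            outs.append(model(Tensor(X[lo:lo + batch])).data)
    return np.concatenate(outs, axis=0)


def train(model: SpeciesClassifier, train_set: EmbeddedSet, cfg: TrainConfig,
          test_set: EmbeddedSet | None = None) -> dict:
    """Cross-entropy training; returns per-epoch history and keeps the best
    test-top-1 weights in the model.

    History lists all have one entry per completed epoch; NaN loss aborts
    with diagnostics rather than training on.
    """
    if train_set.y.max() >= model.cfg.n_classes:
        raise ValueError(
            f"label {int(train_set.y.max())} outside n_classes={model.cfg.n_classes}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 23]))
    opt_cls = {"adam": Adam, "sgd": SGD}[cfg.optimizer]
    opt = opt_cls(model.parameters(), lr=cfg.lr)
    history: dict = {"train_loss": [], "train_top1": [],
                     "test_loss": [], "test_top1": []}
    best = {"top1": -1.0, "state": None, "epoch": -1}
    N = len(train_set)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(N)
        losses, hits = [], 0
        for lo in range(0, N, cfg.batch):
            idx = order[lo:lo + cfg.batch]
            xb = Tensor(train_set.X[idx])
            yb = train_set.y[idx]
            logits = model(xb)
            loss = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // cfg.batch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            hits += int((logits.data.argmax(axis=1) == yb).sum())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_top1"].append(100.0 * hits / N)
        if test_set is not None:
            z = _logits_in_batches(model, test_set.X)
            tloss = softmax_cross_entropy(Tensor(z), test_set.y).item()
            t1 = 100.0 * float((z.argmax(axis=1) == test_set.y).mean())
            history["test_loss"].append(float(tloss))
            history["test_top1"].append(t1)
            if t1 > best["top1"]:
                best = {"top1": t1, "state": model.state_dict(), "epoch": epoch}
            if cfg.stop_at_val_top1 is not None and t1 >= cfg.stop_at_val_top1:
                break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
        history["best_epoch"] = best["epoch"]
        history["best_test_top1"] = best["top1"]
    return history


def evaluate_topk(model: SpeciesClassifier, test_set: EmbeddedSet,
                  ks: Sequence[int] = (1, 5)) -> EvalReport:
    """Top-k accuracies (percent) plus genus-level scores derived from the
    predicted species' genus."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    z = _logits_in_batches(model, test_set.X)
    return report_from_logits(z, test_set, ks)


def report_from_logits(z: np.ndarray, test_set: EmbeddedSet,
                       ks: Sequence[int] = (1, 5)) -> EvalReport:
    ks = sorted(set(ks))
    C = z.shape[1]
    topk = predict_topk(z, min(max(ks), C))  # (N, kmax) label ids
    truth = test_set.y[:, None]
    acc: dict[int, float] = {}
    per_record: dict[int, np.ndarray] = {}
    for k in ks:
        hits = (topk[:, :min(k, C)] == truth).any(axis=1)
        per_record[k] = hits
        acc[k] = 100.0 * float(hits.mean())
    genus_acc: dict[int, float | None] = {}
    if test_set.genus_of:
        names = test_set.species_names
        true_gen = np.asarray([test_set.genus_of.get(s, "") for s in test_set.species])
        pred_gen = np.vectorize(lambda i: test_set.genus_of.get(names[i], ""))(topk)
        for k in ks:
            genus_acc[k] = 100.0 * float(
                (pred_gen[:, :k] == true_gen[:, None]).any(axis=1).mean()
            )
    else:
        genus_acc = {k: None for k in ks}
    return EvalReport(acc, genus_acc, len(test_set), per_record)


def head_tail_eval(model: SpeciesClassifier, test_set: EmbeddedSet,
                   train_abundance: dict[str, int],
                   cutpoints: Sequence[int] = (50, 100, 500),
                   ks: Sequence[int] = (1, 5)) -> HeadTailReport:
    """HEAD (train count >= cut) vs TAIL (< cut) accuracies per cutpoint.

    ``train_abundance`` must be computed on the training set — the long-tail
    profile that drives the partition is a property of what the model saw.
    Empty parts are flagged rather than reported as 0%.
    """
    for c in cutpoints:
        if c <= 0:
            raise ValueError(f"cutpoint must be positive, got {c}")
    report = evaluate_topk(model, test_set, ks)
    counts = np.asarray([train_abundance.get(s, 0) for s in test_set.species])
    parts: dict[tuple[int, str], dict] = {}
    for c in cutpoints:
        for name, mask in (("head", counts >= c), ("tail", counts < c)):
            if not mask.any():
                parts[(c, name)] = {"empty": True, "n": 0}
                continue
            stats = {"empty": False, "n": int(mask.sum())}
            for k in sorted(set(ks)):
                stats[f"top{k}"] = 100.0 * float(report.per_record_hits[k][mask].mean())
            parts[(c, name)] = stats
    return HeadTailReport(list(cutpoints), parts)


def subsample_training(train_set: Dataset, fraction: float, seed: int = 0) -> Dataset:
    """Stratified per-species subsample of round(n * fraction), clamped >= 1."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return train_set
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(train_set.records):
        by_species.setdefault(rec.taxonomy.species, []).append(i)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 29]))
    keep: list[int] = []
    for sp in sorted(by_species):
        idx = by_species[sp]
        n_keep = max(1, round(len(idx) * fraction))
        chosen = rng.permutation(len(idx))[:n_keep]
        keep.extend(idx[c] for c in chosen)
    return train_set.subset(sorted(keep))


def run_ablation(
    grid: dict[str, Sequence],
    run_point: Callable[..., EvalReport],
) -> pd.DataFrame:
    """Cartesian-product experiment runner.

    ``grid`` maps parameter names (e.g. k, variant, shallow_layers,
    fraction, seed) to value lists; ``run_point`` receives one keyword per
    grid axis and returns an :class:`EvalReport`.  One row per grid point.
    """
    axes = sorted(grid)
    rows = []
    for values in itertools.product(*(grid[a] for a in axes)):
        point = dict(zip(axes, values))
        report = run_point(**point)
        row = dict(point)
        for k, v in report.topk_accuracy.items():
            row[f"top{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
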