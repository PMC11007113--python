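"""Per-token embeddings for k-mer id streams.

Three interchangeable providers turn an id stream into an (L' x d) real
matrix, one row per content token:

* :class:`MLMEmbedder` — a BERT-style encoder trained here with the masked
  language-modeling objective only (no next-sentence prediction);
* :class:`TableEmbedder` — a token -> vector table imported from any
  externally trained DNA language model checkpoint export;
* :class:`HashEmbedder` — a deterministic random-projection stub for tests
  and desk-scale runs: every k-mer always maps to the same fixed vector.

Streams longer than the encoder window are cut into overlapping windows,
embedded independently, and stitched back with overlap rows averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import h5py
import numpy as np

from .nn import no_grad, softmax_cross_entropy
from .nn.optim import Adam
from .nn.transformer import TransformerEncoder
from .tokens import (
    CLS, MASK, PAD, SEP, SPECIAL_TOKENS, Vocabulary,
    chunk_windows, reassemble_rows, window_starts,
)


@dataclass
class EmbedderConfig:
    """Hyperparameters of the MLM embedder.

    ``d_model`` defaults to the usual base-encoder width; desk-scale runs
    shrink it.  ``mask_rate`` is the fraction of content tokens hidden per
    batch; with ``span_mask`` each pick hides k contiguous tokens (adjacent
    k-mers share bases, so single-token masking leaks the answer).
    """

    d_model: int = 768
    n_layers: int = 4
    n_heads: int = 8
    max_tokens: int = 512
    mask_rate: float = 0.15
    span_mask: bool = True
    epochs: int = 5
    batch: int = 16
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mask_rate < 1:
            raise ValueError("mask_rate must lie in (0, 1)")


@dataclass(frozen=True)
class EmbeddingMatrix:
    """(L' tokens x d_model) real matrix for one source sequence."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite embedding for {self.source_id!r}")


class EmbeddingProvider(Protocol):
    vocab: Vocabulary
    d_model: int
    max_tokens: int
    fingerprint: str

    def embed_window(self, ids: np.ndarray) -> np.ndarray:
        """Rows for one window of content ids (no specials in, none out)."""


class HashEmbedder:
    """Fixed seeded random vectors per token id — pure, collision-free in practice."""

    def __init__(self, vocab: Vocabulary, d_model: int = 32, seed: int = 0,
                 max_tokens: int = 512):
        self.vocab = vocab
        self.d_model = d_model
        self.max_tokens = max_tokens
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, len(vocab)]))
        self.table = rng.standard_normal((len(vocab), d_model)) / np.sqrt(d_model)
        self.fingerprint = f"hash/{vocab.fingerprint}/d={d_model}/seed={seed}"

    def embed_window(self, ids: np.ndarray) -> np.ndarray:
        if ids.max(initial=0) >= len(self.vocab):
            raise ValueError("token id outside provider vocabulary")
        return self.table[np.asarray(ids, dtype=np.int64)]


class TableEmbedder:
    """token -> vector table loaded from a TSV export of an external checkpoint."""

    def __init__(self, vocab: Vocabulary, table: dict[str, np.ndarray],
                 max_tokens: int = 512, source: str = "table"):
        dims = {len(v) for v in table.values()}
        if len(dims) != 1:
            raise ValueError("inconsistent vector widths in embedding table")
        self.vocab = vocab
        self.d_model = dims.pop()
        self.max_tokens = max_tokens
        self.table = np.zeros((len(vocab), self.d_model))
        missing = 0
        for tok, vec in table.items():
            idx = vocab.token_to_id.get(tok)
            if idx is None:
                missing += 1
                continue
            self.table[idx] = vec
        self.fingerprint = f"{source}/{vocab.fingerprint}/d={self.d_model}"

    @classmethod
    def from_tsv(cls, vocab: Vocabulary, path: str | Path) -> "TableEmbedder":
        table: dict[str, np.ndarray] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                table[parts[0]] = np.asarray([float(v) for v in parts[1:]])
        return cls(vocab, table, source=str(path))

    def embed_window(self, ids: np.ndarray) -> np.ndarray:
        return self.table[np.asarray(ids, dtype=np.int64)]


class MLMEmbedder:
    """Transformer encoder trained with masked-language modeling only."""

    def __init__(self, vocab: Vocabulary, cfg: EmbedderConfig):
        self.vocab = vocab
        self.cfg = cfg
        self.d_model = cfg.d_model
        self.max_tokens = cfg.max_tokens
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 11]))
        self.encoder = TransformerEncoder(
            vocab_size=len(vocab), d_model=cfg.d_model, n_layers=cfg.n_layers,
            n_heads=cfg.n_heads, max_len=cfg.max_tokens, rng=rng,
        )
        self.fingerprint = (f"mlm/{vocab.fingerprint}/d={cfg.d_model}"
                            f"/L={cfg.n_layers}/seed={cfg.seed}")

    def embed_window(self, ids: np.ndarray) -> np.ndarray:
        framed = np.concatenate([[CLS], ids, [SEP]])[None, :]
        self.encoder.eval()
        with no_grad():
            hidden = self.encoder.hidden(framed)
        return hidden.data[0, 1:-1]  # drop [CLS]/[SEP] rows


def _mask_batch(batch: np.ndarray, valid: np.ndarray, cfg: EmbedderConfig,
                span: int, n_regular: int, rng: np.random.Generator):
    """BERT-style corruption: returns (corrupted ids, target mask bool array)."""
    masked = np.zeros_like(valid)
    corrupted = batch.copy()
    B, L = batch.shape
    for b in range(B):
        positions = np.flatnonzero(valid[b])
        n_target = max(1, int(round(cfg.mask_rate * len(positions))))
        if cfg.span_mask and span > 1:
            # keep laying spans until the target count is covered, then trim
            # a random excess so the measured fraction matches mask_rate
            chosen: set[int] = set()
            attempts = 0
            while len(chosen) < n_target and attempts < 4 * len(positions):
                s = int(rng.integers(len(positions)))
                chosen.update(positions[s:s + span].tolist())
                attempts += 1
            chosen_arr = np.asarray(sorted(chosen))
            if len(chosen_arr) > n_target:
                keep = rng.choice(len(chosen_arr), size=n_target, replace=False)
                chosen_arr = chosen_arr[np.sort(keep)]
        else:
            chosen_arr = positions[rng.choice(len(positions),
                                              size=min(n_target, len(positions)),
                                              replace=False)]
        masked[b, chosen_arr] = True
        # 80% -> [MASK], 10% -> random regular token, 10% -> unchanged
        roll = rng.random(len(chosen_arr))
        to_mask = chosen_arr[roll < 0.8]
        to_rand = chosen_arr[(roll >= 0.8) & (roll < 0.9)]
        corrupted[b, to_mask] = MASK
        corrupted[b, to_rand] = rng.integers(len(SPECIAL_TOKENS),
                                             len(SPECIAL_TOKENS) + n_regular,
                                             size=len(to_rand))
    return corrupted, masked


def train_mlm(corpus: list[np.ndarray], cfg: EmbedderConfig,
              vocab: Vocabulary) -> tuple[MLMEmbedder, dict]:
    """Train the encoder on MLM loss over a corpus of content-id streams.

    Returns the embedder plus a history dict with per-epoch mean loss,
    masked-token accuracy, and the measured masked fraction.
    """
    if not corpus:
        raise ValueError("empty corpus")
    embedder = MLMEmbedder(vocab, cfg)
    model = embedder.encoder
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 13]))
    opt = Adam(model.parameters(), lr=cfg.lr)
    n_regular = len(vocab) - len(SPECIAL_TOKENS)
    capacity = cfg.max_tokens - 2
    streams = [np.asarray(s[:capacity], dtype=np.int64) for s in corpus]
    history = {"loss": [], "masked_accuracy": [], "masked_fraction": []}
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(streams))
        losses, n_hit, n_masked, n_tok = [], 0, 0, 0
        for lo in range(0, len(order), cfg.batch):
            idx = order[lo:lo + cfg.batch]
            seqs = [streams[i] for i in idx]
            L = max(len(s) for s in seqs) + 2
            batch = np.full((len(seqs), L), PAD, dtype=np.int64)
            valid = np.zeros((len(seqs), L), dtype=bool)
            for b, s in enumerate(seqs):
                batch[b, 0] = CLS
                batch[b, 1:1 + len(s)] = s
                batch[b, 1 + len(s)] = SEP
                valid[b, 1:1 + len(s)] = True
            corrupted, masked = _mask_batch(batch, valid, cfg, vocab.k,
                                            n_regular, rng)
            attend = batch != PAD
            model.train()
            logits = model.mlm_logits(corrupted, attend)
            rows = np.argwhere(masked)
            sel = logits[rows[:, 0], rows[:, 1]]
            targets = batch[masked]
            loss = softmax_cross_entropy(sel, targets)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            preds = sel.data.argmax(axis=-1)
            n_hit += int((preds == targets).sum())
            n_masked += int(masked.sum())
            n_tok += int(valid.sum())
        history["loss"].append(float(np.mean(losses)))
        history["masked_accuracy"].append(n_hit / max(n_masked, 1))
        history["masked_fraction"].append(n_masked / max(n_tok, 1))
    return embedder, history


def embed(ids: np.ndarray, provider: EmbeddingProvider, overlap: int = 64,
          source_id: str = "") -> EmbeddingMatrix:
    """Embed a content-id stream: window, embed each window, reassemble.

    Overlap rows (shared by consecutive windows) are averaged, so the output
    always has exactly one row per input token.
    """
    ids = np.asarray(ids, dtype=np.int64)
    if len(ids) == 0:
        raise ValueError("cannot embed an empty token stream")
    windows = chunk_windows(ids, provider.max_tokens, overlap)
    starts = window_starts(len(ids), provider.max_tokens, overlap)
    rows = [provider.embed_window(w) for w in windows]
    return EmbeddingMatrix(reassemble_rows(rows, starts, len(ids)), source_id)


def save_embeddings(path: str | Path, mats: dict[str, EmbeddingMatrix],
                    provider_fingerprint: str, k: int) -> None:
    """HDF5 container keyed by record id, with a JSON sidecar of provenance."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for rid, mat in mats.items():
            h5.create_dataset(rid, data=mat.values.astype(np.float32))
    d_model = next(iter(mats.values())).values.shape[1] if mats else 0
    sidecar = {"k": k, "d_model": d_model, "provider": provider_fingerprint,
               "n_records": len(mats)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_embeddings(path: str | Path) -> dict[str, EmbeddingMatrix]:
    out: dict[str, EmbeddingMatrix] = {}
    with h5py.File(path, "r") as h5:
        for rid in h5:
            out[rid] = EmbeddingMatrix(np.asarray(h5[rid], dtype=np.float64), rid)
    return out
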