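"""k-mer tokenization: sequences -> overlapping k-mer token streams -> ids.

A 16S sequence is read as a biolinguistic text whose words are its
overlapping k-mers (stride 1), so a length-L sequence yields L-k+1 tokens.
The vocabulary holds all 4^k DNA k-mers plus the five BERT-style special
tokens; any k-mer containing a non-ACGT symbol encodes to [UNK].

Long sequences (~1498 tokens at k=3 on a 1500 bp gene) exceed a 512-token
encoder window, so :func:`chunk_windows` cuts the id stream into overlapping
windows that :func:`reassemble_rows` later stitches back losslessly
(overlap rows averaged by the embedding layer).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

SPECIAL_TOKENS = ("[CLS]", "[MASK]", "[PAD]", "[UNK]", "[SEP]")
CLS, MASK, PAD, UNK, SEP = range(5)  # fixed ids, documented contract

_BASES = "ACGT"


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> id map over the 5 specials then 4^k k-mers (lexicographic)."""

    k: int
    token_to_id: dict[str, int] = field(repr=False)
    id_to_token: tuple[str, ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.id_to_token)

    def encode_token(self, token: str) -> int:
        return self.token_to_id.get(token, UNK)

    def decode_id(self, idx: int) -> str:
        return self.id_to_token[idx]

    @property
    def fingerprint(self) -> str:
        return f"kmer-vocab/k={self.k}/size={len(self)}"


def build_vocab(k: int) -> Vocabulary:
    """All 4^k DNA k-mers after the five special tokens; deterministic order."""
    if not 1 <= k <= 8:
        raise ValueError(f"k must be in 1..8, got {k}")
    tokens = list(SPECIAL_TOKENS) + [
        "".join(t) for t in itertools.product(_BASES, repeat=k)
    ]
    return Vocabulary(
        k=k,
        token_to_id={t: i for i, t in enumerate(tokens)},
        id_to_token=tuple(tokens),
    )


@dataclass(frozen=True)
class TokenSeq:
    """Overlapping k-mer tokens of one sequence (no specials, no padding)."""

    tokens: tuple[str, ...]
    k: int

    def __len__(self) -> int:
        return len(self.tokens)


def kmerize(seq: str, k: int) -> TokenSeq:
    """Sliding window of width k, stride 1, left to right.

    A sequence shorter than k yields an empty token stream with a warning.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(seq) < k:
        warnings.warn(f"sequence of length {len(seq)} is shorter than k={k}; "
                      "producing an empty token stream", stacklevel=2)
        return TokenSeq((), k)
    return TokenSeq(tuple(seq[i:i + k] for i in range(len(seq) - k + 1)), k)


def encode(ts: TokenSeq, vocab: Vocabulary, add_specials: bool = False) -> np.ndarray:
    """Token ids under ``vocab``; unknown/ambiguous k-mers map to [UNK].

    With ``add_specials``, [CLS] is prepended and [SEP] appended.
    """
    if ts.k != vocab.k:
        raise ValueError(f"token k={ts.k} does not match vocabulary k={vocab.k}")
    ids = [vocab.encode_token(t) for t in ts.tokens]
    if add_specials:
        ids = [CLS] + ids + [SEP]
    return np.asarray(ids, dtype=np.int64)


def decode(ids: np.ndarray, vocab: Vocabulary) -> list[str]:
    return [vocab.decode_id(int(i)) for i in ids]


def chunk_windows(ids: np.ndarray, max_tokens: int = 512, overlap: int = 64) -> list[np.ndarray]:
    """Cut a content-id stream into windows of <= max_tokens - 2 ids.

    Two slots are reserved for [CLS]/[SEP] added at embedding time.
    Successive windows share ``overlap`` ids; :func:`reassemble_rows`
    averages the duplicated rows, so the round trip is lossless.
    """
    capacity = max_tokens - 2
    if overlap >= capacity:
        raise ValueError(f"overlap {overlap} must be < window capacity {capacity}")
    ids = np.asarray(ids)
    n = len(ids)
    if n <= capacity:
        return [ids]
    step = capacity - overlap
    windows = []
    start = 0
    while start < n:
        windows.append(ids[start:start + capacity])
        if start + capacity >= n:
            break
        start += step
    return windows


def reassemble_ids(windows: list[np.ndarray], overlap: int) -> np.ndarray:
    """Inverse of :func:`chunk_windows`: drop each window's leading overlap."""
    if len(windows) == 1:
        return np.asarray(windows[0])
    parts = [windows[0]] + [w[overlap:] for w in windows[1:]]
    return np.concatenate(parts)


def window_starts(n: int, max_tokens: int = 512, overlap: int = 64) -> list[int]:
    """Start offsets matching :func:`chunk_windows` on a length-n stream."""
    capacity = max_tokens - 2
    if n <= capacity:
        return [0]
    step = capacity - overlap
    starts = []
    start = 0
    while start < n:
        starts.append(start)
        if start + capacity >= n:
            break
        start += step
    return starts


def reassemble_rows(
    rows_per_window: list[np.ndarray],
    starts: list[int],
    total: int,
) -> np.ndarray:
    """Stitch per-window row matrices back to one (total x d) matrix.

    Rows covered by several windows (the overlaps) are averaged.
    """
    d = rows_per_window[0].shape[1]
    acc = np.zeros((total, d), dtype=np.float64)
    hits = np.zeros(total, dtype=np.int64)
    for rows, s in zip(rows_per_window, starts):
        acc[s:s + len(rows)] += rows
        hits[s:s + len(rows)] += 1
    if (hits == 0).any():
        raise ValueError("windows do not cover the full token stream")
    return (acc / hits[:, None]).astype(rows_per_window[0].dtype)
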