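"""Reference-database preprocessing: ambiguity resolution, abundance-based
replication of rare species, and the stratified 90/10 split.

Curated 16S databases are extremely imbalanced — many species contribute a
single sequence.  Two steps address this before training:

1. every IUPAC ambiguity code (N, R, Y, ...) is replaced by a concrete base
   drawn uniformly from the code's set, so downstream k-mers never hit [UNK];
2. species with fewer than ``high_abundance_threshold`` (default 11)
   sequences are replicated according to a count-banded table — a species
   with n reads ends up with n x factor(n) reads.  Each replicated copy
   re-resolves its ambiguity codes independently, so copies of
   ambiguity-free sequences are exact duplicates.

The default bands: 1-2 reads -> x12, 3-5 -> x4, 6-10 -> x2, >= 11 -> x1.

Everything here is a pure function of (input, seed): per-species RNG streams
are derived from (seed, species label), so results do not depend on record
order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .silva import AMBIGUITY_CODES, IUPAC_CODES, Dataset, SequenceRecord

#: (low, high) inclusive count band -> total replication factor.
DEFAULT_REPLICATION_TABLE: dict[tuple[int, int], int] = {
    (1, 2): 12,
    (3, 5): 4,
    (6, 10): 2,
}

DEFAULT_HIGH_ABUNDANCE_THRESHOLD = 11


@dataclass
class PreprocessConfig:
    """Replication banding and RNG seed for database preprocessing."""

    high_abundance_threshold: int = DEFAULT_HIGH_ABUNDANCE_THRESHOLD
    replication_table: dict[tuple[int, int], int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATION_TABLE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        covered = sorted(self.replication_table)
        need = self.high_abundance_threshold - 1
        flat: list[int] = []
        for lo, hi in covered:
            flat.extend(range(lo, hi + 1))
        if flat != list(range(1, need + 1)):
            raise ValueError(
                "replication bands must be disjoint and cover "
                f"1..{need}; got {covered}"
            )


@dataclass(frozen=True)
class SplitResult:
    train: Dataset
    test: Dataset
    test_fraction: float = 0.10


def count_per_species(ds: Dataset) -> dict[str, int]:
    """Exact per-species read multiplicities (sums to ``len(ds)``)."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    counts: dict[str, int] = {}
    for rec in ds.records:
        sp = rec.taxonomy.species
        counts[sp] = counts.get(sp, 0) + 1
    return counts


def replication_factor(n: int, cfg: PreprocessConfig | None = None) -> int:
    """Total multiplier applied to every read of a species with ``n`` reads."""
    cfg = cfg or PreprocessConfig()
    if n <= 0:
        raise ValueError(f"species read count must be positive, got {n}")
    if n >= cfg.high_abundance_threshold:
        return 1
    for (lo, hi), factor in cfg.replication_table.items():
        if lo <= n <= hi:
            return factor
    raise ValueError(f"count {n} not covered by replication table")  # pragma: no cover


def _species_rng(seed: int, species: str) -> np.random.Generator:
    # CRC32 keeps the stream stable across processes (unlike hash()).
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(species.encode())])
    )


def resolve_ambiguous(seq: str, rng: np.random.Generator) -> str:
    """Replace each ambiguity code with a base drawn uniformly from its set.

    Length and all unambiguous positions are preserved; a non-IUPAC
    character raises ``ValueError``.
    """
    out = list(seq)
    for i, ch in enumerate(out):
        options = IUPAC_CODES.get(ch)
        if options is None:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
        if len(options) > 1:
            out[i] = options[rng.integers(len(options))]
    return "".join(out)


def has_ambiguity(seq: str) -> bool:
    return any(ch in AMBIGUITY_CODES for ch in seq)


def balance_dataset(ds: Dataset, cfg: PreprocessConfig | None = None) -> Dataset:
    """Ambiguity-resolve every read and replicate rare species per the band table.

    A species with n < threshold reads contributes n x factor(n) output reads
    (each copy independently ambiguity-resolved); n >= threshold species are
    kept once.  Output contains zero ambiguity codes.  Replica ids get
    ``.rep1``, ``.rep2``, ... suffixes.
    """
    cfg = cfg or PreprocessConfig()
    counts = count_per_species(ds)
    out: list[SequenceRecord] = []
    for rec in ds.records:
        sp = rec.taxonomy.species
        factor = replication_factor(counts[sp], cfg)
        # stream keyed by record id: output invariant to record order
        rng = _species_rng(cfg.seed, f"{sp}|{rec.id}")
        for copy in range(factor):
            seq = resolve_ambiguous(rec.sequence, rng)
            rid = rec.id if copy == 0 else f"{rec.id}.rep{copy}"
            out.append(SequenceRecord(rid, seq, rec.taxonomy))
    return Dataset(out, dict(ds.label_index))


def stratified_split(
    ds: Dataset,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> SplitResult:
    """Per-species train/test partition with every species in both parts.

    Each species with n reads sends ``round(n * test_fraction)`` reads to the
    test set, clamped to [1, n-1]; a singleton species is an error (run
    :func:`balance_dataset` first — its factors are >= 2 below the
    threshold).  Deterministic given the seed, independent of record order.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(ds.records):
        by_species.setdefault(rec.taxonomy.species, []).append(i)
    singletons = [sp for sp, idx in by_species.items() if len(idx) < 2]
    if singletons:
        raise ValueError(
            f"{len(singletons)} species have a single read (e.g. {singletons[0]!r}); "
            "run balance_dataset first so every species can appear in both parts"
        )
    train_idx: list[int] = []
    test_idx: list[int] = []
    for sp in sorted(by_species):
        # permute positions in id-sorted order: invariant to record order
        idx = sorted(by_species[sp], key=lambda i: ds.records[i].id)
        n = len(idx)
        n_test = int(np.clip(round(n * test_fraction), 1, n - 1))
        perm = _species_rng(seed, sp).permutation(n)
        chosen = set(perm[:n_test])
        for pos, i in enumerate(idx):
            (test_idx if pos in chosen else train_idx).append(i)
    return SplitResult(ds.subset(sorted(train_idx)), ds.subset(sorted(test_idx)),
                       test_fraction)
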