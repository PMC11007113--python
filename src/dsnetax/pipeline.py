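"""End-to-end plumbing: dataset -> token ids -> embeddings -> EmbeddedSet,
plus the desk-scale benchmark community used throughout the test suite.

The benchmark emulates a well-separated mock community: 20 species at 10%
pairwise divergence, 30 reads each, 400 bp — small enough to train on one
CPU in minutes, hard enough that a broken model cannot pass.
"""

from __future__ import annotations

import numpy as np

from .embed import EmbeddingProvider, HashEmbedder, embed
from .model import DSNetaxConfig, SplitAttnConfig
from .preprocess import PreprocessConfig, balance_dataset, count_per_species, stratified_split
from .silva import Dataset
from .simulate import AbundanceConfig, SimConfig, simulate_community
from .tokens import Vocabulary, build_vocab, encode, kmerize
from .train import EmbeddedSet, stack_embeddings


def encode_dataset(ds: Dataset, vocab: Vocabulary) -> list[np.ndarray]:
    """Content-token id stream per record (no specials)."""
    return [encode(kmerize(r.sequence, vocab.k), vocab) for r in ds.records]


def embed_dataset(ds: Dataset, provider: EmbeddingProvider,
                  overlap: int = 64) -> EmbeddedSet:
    """Embed every record and stack into a training-ready array set."""
    vocab = provider.vocab
    mats = [embed(ids, provider, overlap=overlap, source_id=r.id).values
            for ids, r in zip(encode_dataset(ds, vocab), ds.records)]
    species = [r.taxonomy.species for r in ds.records]
    return stack_embeddings(mats, ds.labels(), species, ds.species_names,
                            ds.genus_of_species())


def desk_model_config(n_classes: int, variant: str = "dsnetax",
                      shallow_layers: int = 3, seed: int = 0) -> DSNetaxConfig:
    """Small-width architecture for CPU-scale runs (full topology, thin channels)."""
    return DSNetaxConfig(
        n_classes=n_classes,
        variant=variant,
        stage_blocks=(2, 3, 2, 2),
        stage_widths=(8, 8, 16, 16),
        stem_width=8,
        shallow_layers=shallow_layers,
        shallow_width=8,
        split_attn=SplitAttnConfig(cardinality=1, radix=2, reduction=4),
        seed=seed,
    )


def benchmark_sim_config(seed: int = 0, n_species: int = 20, reads: int = 30,
                         length: int = 400, divergence: float = 0.10) -> SimConfig:
    """The learning-sanity mock community: uniform abundance, mild read noise."""
    return SimConfig(
        n_species=n_species,
        species_per_genus=2,
        seq_length=length,
        inter_species_divergence=divergence,
        within_species_rate=0.01,
        ambiguity_rate=0.005,
        abundance=AbundanceConfig(max_count=reads, min_count=reads),
        seed=seed,
    )


def benchmark_data(seed: int = 0, k: int = 3, d_model: int = 32,
                   **sim_kwargs) -> tuple[EmbeddedSet, EmbeddedSet, Dataset, Dataset]:
    """Simulate, preprocess, split 90/10 and hash-embed the benchmark community.

    Returns (train embedded, test embedded, train dataset, test dataset).
    """
    cfg = benchmark_sim_config(seed=seed, **sim_kwargs)
    ds, _refs = simulate_community(cfg)
    ds = balance_dataset(ds, PreprocessConfig(seed=seed))
    split = stratified_split(ds, test_fraction=0.10, seed=seed)
    vocab = build_vocab(k)
    provider = HashEmbedder(vocab, d_model=d_model, seed=seed)
    return (embed_dataset(split.train, provider),
            embed_dataset(split.test, provider),
            split.train, split.test)


def train_abundance(train_ds: Dataset) -> dict[str, int]:
    return count_per_species(train_ds)
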