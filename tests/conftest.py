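"""Shared fixtures: small simulated communities and one trained benchmark model.

The expensive artifacts (the 20-species benchmark and the model trained on
it) are session-scoped so the learning-sanity, top-k and head/tail tests
share a single training run.
"""

from __future__ import annotations

import pytest

from dsnetax.model import build_model
from dsnetax.pipeline import benchmark_data, desk_model_config
from dsnetax.silva import Dataset, SequenceRecord, Taxonomy
from dsnetax.train import TrainConfig, train


def make_taxonomy(species: str, genus: str = "G") -> Taxonomy:
    return Taxonomy(("Bacteria", "P", "C", "O", "F", genus, species))


def make_dataset(species_sizes: dict[str, int], seq: str = "ACGTACGTAC") -> Dataset:
    """One species per key with the given number of identical-sequence reads."""
    records = []
    for sp, n in species_sizes.items():
        for i in range(n):
            records.append(SequenceRecord(f"{sp}_{i}", seq, make_taxonomy(sp)))
    return Dataset(records)


@pytest.fixture(scope="session")
def benchmark():
    """20 species x 30 reads, 400 bp, 10% divergence, hash embeddings d=32."""
    train_set, test_set, train_ds, test_ds = benchmark_data(seed=1)
    return {"train": train_set, "test": test_set,
            "train_ds": train_ds, "test_ds": test_ds}


@pytest.fixture(scope="session")
def trained_benchmark_model(benchmark):
    """Small-width deep-shallow model trained on the benchmark (<= 30 epochs)."""
    model = build_model(desk_model_config(n_classes=20, seed=1))
    history = train(
        model, benchmark["train"],
        TrainConfig(epochs=30, batch=32, seed=1, stop_at_val_top1=100.0),
        test_set=benchmark["test"],
    )
    return model, history
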