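"""Top-k evaluation, head/tail bookkeeping, subsampling and the ablation grid."""

import numpy as np
import pytest

from dsnetax.model import build_model
from dsnetax.pipeline import desk_model_config, embed_dataset
from dsnetax.embed import HashEmbedder
from dsnetax.tokens import build_vocab
from dsnetax.train import (
    EmbeddedSet, EvalReport, TrainConfig, evaluate_topk, head_tail_eval,
    report_from_logits, run_ablation, subsample_training, train,
)
from dsnetax.simulate import AbundanceConfig, SimConfig, simulate_community
from dsnetax.preprocess import count_per_species, stratified_split

from conftest import make_dataset


def toy_embedded(n_per_class: dict[int, int], L=8, d=4, seed=0) -> EmbeddedSet:
    rng = np.random.default_rng(seed)
    names = [f"sp{c}" for c in range(max(n_per_class) + 1)]
    X, y, species = [], [], []
    for c, n in sorted(n_per_class.items()):
        for _ in range(n):
            X.append(rng.standard_normal((1, L, d)))
            y.append(c)
            species.append(names[c])
    return EmbeddedSet(np.stack(X), np.asarray(y), species, names,
                       {n: "G" + n[-1] for n in names})


class TestEvalReport:
    def test_perfect_predictor_scores_100(self):
        es = toy_embedded({0: 3, 1: 3, 2: 3})
        z = np.eye(3)[es.y] * 10.0
        rep = report_from_logits(z, es, ks=(1, 3))
        assert rep.topk_accuracy[1] == 100.0
        assert rep.topk_accuracy[3] == 100.0
        assert rep.genus_topk_accuracy[1] == 100.0

    def test_random_logits_match_binomial_expectation(self):
        """Uniform-random logits over C=20: top-k accuracy ~ 100k/C within 3 sigma."""
        C, n = 20, 2000
        rng = np.random.default_rng(123)
        es = toy_embedded({c: n // C for c in range(C)})
        z = rng.standard_normal((n, C))
        rep = report_from_logits(z, es, ks=(1, 5))
        for k in (1, 5):
            p = k / C
            sigma = 100 * np.sqrt(p * (1 - p) / n)
            assert abs(rep.topk_accuracy[k] - 100 * p) < 3 * sigma

    def test_topk_nesting(self):
        rng = np.random.default_rng(7)
        es = toy_embedded({c: 10 for c in range(6)})
        z = rng.standard_normal((60, 6))
        rep = report_from_logits(z, es, ks=(1, 3, 5))
        assert rep.topk_accuracy[1] <= rep.topk_accuracy[3] <= rep.topk_accuracy[5]

    def test_decreasing_topk_is_rejected(self):
        with pytest.raises(ValueError):
            EvalReport({1: 50.0, 5: 40.0}, {1: None, 5: None}, 10)

    def test_empty_test_set_rejected(self):
        model = build_model(desk_model_config(n_classes=3))
        es = toy_embedded({0: 1})
        es.X = es.X[:0]
        es.y = es.y[:0]
        es.species = []
        with pytest.raises(ValueError):
            evaluate_topk(model, es)


@pytest.fixture(scope="module")
def setup():
    # long-tailed species: train counts straddle every default cutpoint
    counts = {"sp0": 600, "sp1": 200, "sp2": 80, "sp3": 20}
    es = toy_embedded({c: 10 for c in range(4)}, seed=1)
    model = build_model(desk_model_config(n_classes=4, seed=1))
    abundance = {f"sp{c}": n for c, n in enumerate(counts.values())}
    return model, es, abundance


class TestHeadTail:

    def test_partition_is_complete_per_cutpoint(self, setup):
        model, es, abundance = setup
        rep = head_tail_eval(model, es, abundance)
        for c in (50, 100, 500):
            n_head = rep.parts[(c, "head")]["n"]
            n_tail = rep.parts[(c, "tail")]["n"]
            assert n_head + n_tail == len(es)

    def test_boundary_count_is_head(self, setup):
        model, es, _ = setup
        rep = head_tail_eval(model, es, {"sp0": 50, "sp1": 49, "sp2": 50, "sp3": 51},
                             cutpoints=(50,))
        assert rep.parts[(50, "head")]["n"] == 30  # counts >= 50: sp0, sp2, sp3

    def test_weighted_recombination_equals_overall(self, setup):
        model, es, abundance = setup
        overall = evaluate_topk(model, es, ks=(1,)).topk_accuracy[1]
        rep = head_tail_eval(model, es, abundance, ks=(1,))
        for c in (50, 100, 500):
            h, t = rep.parts[(c, "head")], rep.parts[(c, "tail")]
            acc_h = h.get("top1", 0.0) * h["n"]
            acc_t = t.get("top1", 0.0) * t["n"]
            recombined = (acc_h + acc_t) / (h["n"] + t["n"])
            assert recombined == pytest.approx(overall, abs=1e-9)

    def test_empty_tail_is_flagged_not_zero(self, setup):
        model, es, _ = setup
        rep = head_tail_eval(model, es, {f"sp{c}": 1000 for c in range(4)},
                             cutpoints=(50,))
        assert rep.parts[(50, "tail")] == {"empty": True, "n": 0}
        assert not rep.parts[(50, "head")]["empty"]

    def test_nonpositive_cutpoint_rejected(self, setup):
        model, es, abundance = setup
        with pytest.raises(ValueError):
            head_tail_eval(model, es, abundance, cutpoints=(0,))


class TestSubsample:
    def test_fraction_one_is_identity(self):
        ds = make_dataset({"A": 4, "B": 6})
        assert subsample_training(ds, 1.0, seed=0) is ds

    def test_half_of_ten_is_five(self):
        ds = make_dataset({"A": 10})
        assert len(subsample_training(ds, 0.5, seed=0)) == 5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_every_species_retains_at_least_one(self, seed):
        rng = np.random.default_rng(seed)
        sizes = {f"s{i}": int(rng.integers(1, 12)) for i in range(10)}
        ds = make_dataset(sizes)
        sub = subsample_training(ds, 0.1, seed=seed)
        assert set(count_per_species(sub)) == set(sizes)

    def test_deterministic(self):
        ds = make_dataset({"A": 9, "B": 11})
        a = subsample_training(ds, 0.4, seed=3)
        b = subsample_training(ds, 0.4, seed=3)
        assert [r.id for r in a.records] == [r.id for r in b.records]


class TestTrainLoop:
    def test_history_length_and_loss_decrease(self):
        es = toy_embedded({0: 12, 1: 12}, L=16, d=4, seed=2)
        model = build_model(desk_model_config(n_classes=2, seed=0))
        hist = train(model, es, TrainConfig(epochs=4, batch=8, seed=0))
        assert len(hist["train_loss"]) == 4
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_label_outside_n_classes_rejected(self):
        es = toy_embedded({0: 2, 1: 2, 5: 2})
        model = build_model(desk_model_config(n_classes=3))
        with pytest.raises(ValueError, match="n_classes"):
            train(model, es, TrainConfig(epochs=1, seed=0))


class TestAblationGrid:
    def test_grid_size_and_determinism(self):
        calls = []

        def run_point(**pt):
            calls.append(pt)
            score = 10.0 * pt["k"] + pt["fraction"]
            return EvalReport({1: score, 5: score}, {1: None, 5: None}, 10)

        grid = {"k": [3, 4], "fraction": [0.5, 1.0]}
        t1 = run_ablation(grid, run_point)
        t2 = run_ablation(grid, run_point)
        assert len(t1) == 4
        assert t1.equals(t2)

    def test_variant_smoke_matrix(self):
        """cnn3, resnet34 and the deep-shallow model all train on a tiny set."""
        cfg = SimConfig(n_species=4, species_per_genus=2, seq_length=60,
                        within_species_rate=0.01, ambiguity_rate=0.0,
                        abundance=AbundanceConfig(max_count=6, min_count=6), seed=5)
        ds, _ = simulate_community(cfg)
        res = stratified_split(ds, 0.2, seed=0)
        vocab = build_vocab(3)
        prov = HashEmbedder(vocab, d_model=8, seed=0)
        tr = embed_dataset(res.train, prov)
        te = embed_dataset(res.test, prov)

        def run_point(variant):
            model = build_model(desk_model_config(n_classes=4, variant=variant, seed=0))
            train(model, tr, TrainConfig(epochs=1, batch=8, seed=0))
            return evaluate_topk(model, te, ks=(1,))

        table = run_ablation({"variant": ["cnn3", "resnet34", "dsnetax"]}, run_point)
        assert len(table) == 3
        assert table["top1"].between(0, 100).all()
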