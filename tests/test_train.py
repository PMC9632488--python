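"""Splitting, training loop, evaluation and the ablation procedures."""

import numpy as np
import pytest

from eegfuse.clipping import ClipConfig
from eegfuse.nn import ModelConfig, build_network
from eegfuse.render import ImageSample, RenderConfig
from eegfuse.synthetic import SyntheticConfig, generate_cohort
from eegfuse.train import (
    SplitPolicy,
    evaluate,
    run_augmentation_experiment,
    run_length_experiment,
    split_dataset,
    train,
)


def make_images(n_per_class: int, n_subjects: int = 10, size: int = 16,
                seed: int = 0, n_classes: int = 2, separable: bool = False):
    """Random (or class-separable) uint8 images tagged with round-robin subjects."""
    rng = np.random.default_rng(seed)
    samples = []
    for lab in range(n_classes):
        for i in range(n_per_class):
            px = rng.integers(0, 256, (size, size, 3), dtype=np.uint8)
            if separable:
                # class-dependent mean brightness, an easy learnable cue
                px = (px // 2 + lab * 120).astype(np.uint8)
            subject = f"c{lab}-subj{i % n_subjects}"
            samples.append(ImageSample(px, lab, (subject, 1, 1 + i * size)))
    return samples


class TestSplit:
    def test_fraction_900_of_1000(self):
        samples = make_images(500)
        train_set, test_set, _ = split_dataset(samples, SplitPolicy("paper-faithful", 0.9, 0))
        assert len(train_set) == 900 and len(test_set) == 100
        assert len(train_set) + len(test_set) == len(samples)

    def test_partition_is_disjoint_and_exhaustive(self):
        samples = make_images(40)
        train_set, test_set, _ = split_dataset(samples, SplitPolicy("paper-faithful", 0.8, 3))
        ids = lambda xs: {id(s) for s in xs}
        assert ids(train_set) & ids(test_set) == set()
        assert ids(train_set) | ids(test_set) == ids(samples)

    def test_subject_level_has_zero_leakage(self):
        samples = make_images(60, n_subjects=10)
        for seed in range(5):
            train_set, test_set, _ = split_dataset(
                samples, SplitPolicy("subject-level", 0.9, seed)
            )
            assert {s.subject_id for s in train_set} & {s.subject_id for s in test_set} == set()
            assert len(train_set) + len(test_set) == len(samples)

    def test_same_seed_identical_split(self):
        samples = make_images(30)
        a = split_dataset(samples, SplitPolicy("subject-level", 0.8, 11))
        b = split_dataset(samples, SplitPolicy("subject-level", 0.8, 11))
        assert [s.provenance for s in a[0]] == [s.provenance for s in b[0]]
        assert [s.provenance for s in a[1]] == [s.provenance for s in b[1]]

    def test_single_subject_class_warns(self):
        samples = make_images(4, n_subjects=1)
        with pytest.warns(UserWarning):
            _, test_set, notes = split_dataset(samples, SplitPolicy("subject-level", 0.9, 0))
        assert notes
        assert test_set == []

    def test_invalid_policy_rejected(self):
        with pytest.raises(ValueError):
            SplitPolicy("bogus")
        with pytest.raises(ValueError):
            SplitPolicy(train_fraction=1.0)


class TestTrainLoop:
    CFG = dict(architecture="tiny", n_classes=2, input_size=16, batch_size=16)

    def test_learning_on_separable_images(self):
        samples = make_images(50, size=16, separable=True, seed=1)
        cfg = ModelConfig(**self.CFG, epochs=5, learning_rate=1e-3, seed=0)
        _, net = build_network(cfg)
        history = train(net, samples, cfg)
        assert len(history) == 5
        assert history[-1]["accuracy"] > history[0]["accuracy"]

    def test_zero_learning_rate_freezes_weights(self):
        samples = make_images(10, size=16, seed=2)
        cfg = ModelConfig(**self.CFG, epochs=3, learning_rate=0.0, seed=0)
        _, net = build_network(cfg)
        before = {k: v.copy() for k, v in net.state_arrays().items()}
        history = train(net, samples, cfg)
        for k, v in net.state_arrays().items():
            np.testing.assert_array_equal(v, before[k])
        losses = [h["loss"] for h in history]
        assert max(losses) - min(losses) < 1e-6

    def test_fixed_seed_identical_history(self):
        samples = make_images(20, size=16, seed=3)
        cfg = ModelConfig(**self.CFG, epochs=3, learning_rate=1e-3, seed=5)
        histories = []
        for _ in range(2):
            _, net = build_network(cfg)
            histories.append(train(net, samples, cfg))
        assert histories[0] == histories[1]

    def test_wrong_image_size_rejected(self):
        samples = make_images(4, size=8)
        cfg = ModelConfig(**self.CFG, epochs=1, seed=0)
        _, net = build_network(cfg)
        with pytest.raises(ValueError, match="expects"):
            train(net, samples, cfg)

    def test_empty_train_set_rejected(self):
        cfg = ModelConfig(**self.CFG, epochs=1, seed=0)
        _, net = build_network(cfg)
        with pytest.raises(ValueError, match="empty"):
            train(net, [], cfg)


class TestEvaluate:
    def test_constant_predictor_on_balanced_test(self):
        samples = make_images(20, size=16, seed=4)
        cfg = ModelConfig("tiny", n_classes=2, input_size=16, seed=0)
        _, net = build_network(cfg)
        # force a constant prediction by biasing the final layer hard
        net.layers[-1].weight[:] = 0
        net.layers[-1].bias[:] = np.array([10.0, 0.0], dtype=np.float32)
        report = evaluate(net, samples, 2)
        assert report.accuracy == pytest.approx(0.5)
        assert (report.confusion[:, 1] == 0).all()
        assert report.confusion[:, 0].sum() == len(samples)

    def test_confusion_identities(self):
        samples = make_images(15, size=16, seed=5)
        cfg = ModelConfig("tiny", n_classes=2, input_size=16, seed=1)
        _, net = build_network(cfg)
        report = evaluate(net, samples, 2)
        assert report.confusion.sum() == len(samples)
        np.testing.assert_array_equal(report.confusion.sum(axis=1), report.per_class_counts)
        assert report.accuracy == pytest.approx(
            report.confusion.trace() / report.confusion.sum()
        )

    def test_untrained_net_near_chance(self):
        """Untrained seeded net on a balanced binary test stays inside the
        99% binomial band around 0.5 (n=200 -> [0.409, 0.591])."""
        samples = make_images(100, size=16, seed=6)
        cfg = ModelConfig("tiny", n_classes=2, input_size=16, seed=3)
        _, net = build_network(cfg)
        report = evaluate(net, samples, 2)
        assert 0.409 <= report.accuracy <= 0.591

    def test_tsne_skipped_when_too_small(self):
        samples = make_images(1, size=16, seed=7)  # 2 samples total
        cfg = ModelConfig("tiny", n_classes=2, input_size=16, seed=0)
        _, net = build_network(cfg)
        report = evaluate(net, samples, 2, with_tsne=True)
        assert report.tsne_coords is None
        assert any("t-SNE" in w for w in report.warnings)

    def test_tsne_shape_and_determinism(self):
        samples = make_images(30, size=16, seed=8)
        cfg = ModelConfig("tiny", n_classes=2, input_size=16, seed=0)
        _, net = build_network(cfg)
        r1 = evaluate(net, samples, 2, with_tsne=True, tsne_seed=4)
        r2 = evaluate(net, samples, 2, with_tsne=True, tsne_seed=4)
        assert r1.tsne_coords.shape == (60, 2)
        np.testing.assert_array_equal(r1.tsne_coords, r2.tsne_coords)


FAST_MODEL = dict(architecture="tiny", n_classes=2, input_size=32,
                  learning_rate=1e-3, epochs=2, seed=0)
FAST_RENDER = RenderConfig(width=32, height=32)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(
        SyntheticConfig(duration=3.0, n_records_per_class=4, master_seed=9)
    )


class TestExperiments:
    def test_length_experiment_rows_and_recommendation(self, small_cohort):
        table = run_length_experiment(
            small_cohort, [128, 256], ModelConfig(**FAST_MODEL),
            render_config=FAST_RENDER, policy=SplitPolicy(train_fraction=0.75),
        )
        assert len(table.rows) == 2
        for _, loss, acc in table.rows:
            assert 0.0 <= acc <= 1.0 and loss >= 0.0
        assert table.recommended in {"128", "256"}

    def test_length_experiment_skips_too_long(self, small_cohort):
        table = run_length_experiment(
            small_cohort, [256, 10_000], ModelConfig(**FAST_MODEL),
            render_config=FAST_RENDER, policy=SplitPolicy(train_fraction=0.75),
        )
        assert "skipped" in table.rows[1][0]
        assert np.isnan(table.rows[1][2])

    def test_duplicate_lengths_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="distinct"):
            run_length_experiment(small_cohort, [256, 256], ModelConfig(**FAST_MODEL))

    def test_augmentation_experiment_factor_one_is_aun(self, small_cohort):
        table = run_augmentation_experiment(
            small_cohort, [1], ModelConfig(**FAST_MODEL), window_length=256,
            render_config=FAST_RENDER, policy=SplitPolicy(train_fraction=0.75),
        )
        assert [r[0] for r in table.rows] == ["AU-N"]

    def test_augmentation_sample_counts_match_expected(self, small_cohort):
        from eegfuse.clipping import expected_sample_count, msc_augment

        for C in (1, 4):
            total = sum(
                len(msc_augment(r, ClipConfig(256, C))) for r in small_cohort
            )
            expected = sum(
                expected_sample_count(r.n_samples, 256, C) for r in small_cohort
            )
            assert total == expected
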