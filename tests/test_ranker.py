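"""RankNet math, pair selection, annotator simulation, training mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reticulin_cif.exceptions import CalibrationError, DataError, InvalidArgumentError
from reticulin_cif.ranker import (
    ConvScorer,
    PairwiseComparison,
    TrainConfig,
    calibrate,
    load_model,
    make_model,
    pairwise_accuracy,
    pairwise_loss,
    pairwise_probability,
    preprocess_tiles,
    save_model,
    score_tiles,
    select_pairs,
    simulate_annotators,
    train_round,
)


class TestPairwiseProbability:
    def test_equal_scores_give_half(self):
        assert pairwise_probability(1.3, 1.3) == pytest.approx(0.5)

    def test_saturation(self):
        assert pairwise_probability(600.0, 0.0) == pytest.approx(1.0)
        assert pairwise_probability(0.0, 600.0) == pytest.approx(0.0)

    def test_log3_gap_gives_three_quarters(self):
        assert pairwise_probability(np.log(3.0), 0.0) == pytest.approx(0.75)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.floats(-50, 50, allow_nan=False),
        st.floats(-50, 50, allow_nan=False),
    )
    def test_antisymmetry(self, a, b):
        assert pairwise_probability(a, b) + pairwise_probability(b, a) == pytest.approx(1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pairwise_probability(np.nan, 0.0)


class TestPairwiseLoss:
    def test_uninformed_is_ln2(self):
        s = np.zeros(10)
        y = np.array([1, 0] * 5)
        assert pairwise_loss(s, s, y) == pytest.approx(np.log(2.0))

    def test_confident_correct_tends_to_zero(self):
        assert pairwise_loss([50.0], [0.0], [1]) < 1e-6

    def test_single_pair_quarter_confidence(self):
        # y=1, P=0.75 -> loss = ln(4/3)
        assert pairwise_loss([np.log(3.0)], [0.0], [1]) == pytest.approx(np.log(4.0 / 3.0))

    def test_empty_batch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pairwise_loss([], [], [])


class TestAccuracy:
    def test_ties_count_half(self):
        assert pairwise_accuracy(
            np.array([1.0, 2.0]), np.array([1.0, 1.0]), np.array([1, 1])
        ) == pytest.approx(0.75)


class TestSelectPairs:
    def test_two_tiles_single_pair(self):
        assert select_pairs(None, 2, 1, "uniform", seed=0) == [(0, 1)]

    def test_uncertainty_prefers_small_gap(self):
        model = make_model(input_size=8, channels=(2,), seed=0, in_channels=1)

        class Fixed:
            input_size = 8
            channels = (2,)
            in_channels = 1

            def score(self, x, batch_size=256):
                return np.array([0.0, 0.01, 5.0])

        model.scorer = Fixed()
        pairs = select_pairs(
            model, 3, 3, "uncertainty", seed=0, tile_images=np.zeros((3, 8, 8))
        )
        assert pairs[0] == (0, 1)

    def test_uniform_deterministic(self):
        a = select_pairs(None, 50, 30, "uniform", seed=5)
        b = select_pairs(None, 50, 30, "uniform", seed=5)
        assert a == b
        assert len(set(a)) == 30

    def test_truncation_warns(self):
        with pytest.warns(UserWarning):
            pairs = select_pairs(None, 3, 10, "uniform", seed=0)
        assert len(pairs) == 3

    def test_too_few_tiles(self):
        with pytest.raises(InvalidArgumentError):
            select_pairs(None, 1, 1, "uniform", seed=0)


class TestSimulateAnnotators:
    def test_perfect_concordance_reproduces_oracle(self):
        pairs = [(0, 1), (1, 2), (2, 3)]
        oracle = np.array([1, 0, 1])
        comps, report = simulate_annotators(pairs, oracle, concordance=1.0, seed=0)
        assert [c.label for c in comps] == [1, 0, 1]
        assert report.inter_annotator_agreement == pytest.approx(1.0)

    def test_anti_informative_concordance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_annotators([(0, 1)], np.array([1]), concordance=0.5)

    def test_pairwise_agreement_matches_closed_form(self):
        """Two independent raters at concordance p agree with rate p^2+(1-p)^2."""
        n = 20000
        p = 0.884
        pairs = [(i, i + 1) for i in range(n)]
        oracle = np.zeros(n, dtype=int)
        _, report = simulate_annotators(pairs, oracle, concordance=p, seed=3)
        expected = p**2 + (1 - p) ** 2  # ~0.795
        se = np.sqrt(expected * (1 - expected) / n)
        assert report.inter_annotator_agreement == pytest.approx(expected, abs=4 * se)

    def test_majority_vote_accuracy_matches_binomial(self):
        """Majority of 3 at concordance p is right with rate 3p^2(1-p)+p^3."""
        n = 10000
        p = 0.9
        pairs = [(i, i + 1) for i in range(n)]
        oracle = (np.arange(n) % 2).astype(int)
        _, report = simulate_annotators(pairs, oracle, concordance=p, seed=11)
        expected = 3 * p**2 * (1 - p) + p**3  # 0.972
        assert 0.95 <= report.majority_vs_oracle_accuracy <= 0.99
        se = np.sqrt(expected * (1 - expected) / n)
        assert report.majority_vs_oracle_accuracy == pytest.approx(expected, abs=4 * se)


def toy_brightness_setup(n_tiles=160, size=16, seed=0):
    """Constant-intensity patches whose mean encodes severity."""
    rng = np.random.default_rng(seed)
    sev = rng.random(n_tiles)
    tiles = sev[:, None, None] * 0.8 - 0.4 + rng.normal(0, 0.02, (n_tiles, size, size))
    pairs = select_pairs(None, n_tiles, 700, "uniform", seed=seed + 1)
    comps = [
        PairwiseComparison(i, j, int(sev[i] >= sev[j])) for i, j in pairs
    ]
    return tiles, sev, comps


class TestTraining:
    def test_zero_epochs_is_noop(self):
        tiles, _, comps = toy_brightness_setup()
        model = make_model(input_size=16, channels=(4,), seed=2, in_channels=1)
        before = {k: v.copy() for k, v in model.scorer.params.items()}
        trained, rep = train_round(model, comps, tiles, TrainConfig(epochs=0, seed=3))
        for k in before:
            assert np.array_equal(before[k], trained.scorer.params[k])

    def test_brightness_toy_learns(self):
        tiles, _, comps = toy_brightness_setup()
        model = make_model(input_size=16, channels=(4,), seed=2, in_channels=1)
        trained, rep = train_round(model, comps, tiles, TrainConfig(epochs=5, seed=3))
        assert rep.heldout_accuracy >= 0.95

    def test_shuffled_labels_stay_at_chance(self):
        tiles, _, comps = toy_brightness_setup()
        rng = np.random.default_rng(9)
        shuffled = [
            PairwiseComparison(c.tile_a_id, c.tile_b_id, int(rng.integers(2)))
            for c in comps
        ]
        model = make_model(input_size=16, channels=(4,), seed=2, in_channels=1)
        _, rep = train_round(model, shuffled, tiles, TrainConfig(epochs=5, seed=3))
        assert 0.45 <= rep.heldout_accuracy <= 0.55

    def test_training_reproducible(self):
        tiles, _, comps = toy_brightness_setup()
        accs = []
        for _ in range(2):
            model = make_model(input_size=16, channels=(4,), seed=2, in_channels=1)
            _, rep = train_round(model, comps, tiles, TrainConfig(epochs=3, seed=3))
            accs.append(rep.heldout_accuracy)
        assert accs[0] == accs[1]

    def test_degenerate_pairs_rejected(self):
        tiles = np.zeros((2, 16, 16))
        comps = [PairwiseComparison(0, 0, 1)]
        model = make_model(input_size=16, channels=(4,), seed=0, in_channels=1)
        with pytest.raises(DataError):
            train_round(model, comps, tiles, TrainConfig(seed=0))

    def test_gradients_match_numeric(self):
        net = ConvScorer(input_size=12, channels=(3, 4), seed=1, in_channels=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 12, 12))
        y = np.array([1.0, 0.0])

        def loss():
            s = net.forward(x)
            return pairwise_loss(s[:2], s[2:], y)

        s, cache = net.forward(x, want_cache=True)
        d = s[:2] - s[2:]
        g = (1.0 / (1.0 + np.exp(-d)) - y) / 2
        grads = net.backward(cache, np.concatenate([g, -g]))
        eps = 1e-6
        for key in net.params:
            p = net.params[key]
            idx = tuple(rng.integers(s_) for s_ in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestCalibration:
    def test_reference_max_maps_to_one(self):
        rng = np.random.default_rng(4)
        tiles = rng.normal(size=(20, 16, 16))
        model = make_model(input_size=16, channels=(4,), seed=1, in_channels=1)
        model = calibrate(model, tiles)
        scores = score_tiles(model, tiles)
        assert scores.max() == pytest.approx(1.0)
        assert scores.min() == pytest.approx(0.0)

    def test_degenerate_scores_raise(self):
        tiles = np.zeros((5, 16, 16))
        model = make_model(input_size=16, channels=(4,), seed=1, in_channels=1)
        with pytest.raises(CalibrationError):
            calibrate(model, tiles)

    def test_normalization_is_monotone(self):
        rng = np.random.default_rng(8)
        tiles = rng.normal(size=(30, 16, 16))
        model = make_model(input_size=16, channels=(4,), seed=1, in_channels=1)
        model = calibrate(model, tiles)
        raw = model.scorer.score(tiles)
        cif = score_tiles(model, tiles)
        assert np.array_equal(np.argsort(raw, kind="stable"), np.argsort(cif, kind="stable"))

    def test_uncalibrated_model_refuses_to_score(self):
        model = make_model(input_size=16, channels=(4,), seed=1, in_channels=1)
        with pytest.raises(CalibrationError):
            score_tiles(model, np.zeros((2, 16, 16)))


class TestPreprocessAndPersistence:
    def test_preprocess_shapes_and_range(self):
        tiles = np.full((3, 128, 128), 128, dtype=np.uint8)
        x = preprocess_tiles(tiles, input_size=32)
        assert x.shape == (3, 32, 32, 2)
        assert np.all(np.abs(x) <= 0.5 + 1e-9)

    def test_preprocess_too_small_rejected(self):
        with pytest.raises(InvalidArgumentError):
            preprocess_tiles(np.zeros((1, 16, 16)), input_size=32)

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        tiles = rng.normal(size=(10, 16, 16))
        model = make_model(input_size=16, channels=(4,), seed=1, in_channels=1)
        model = calibrate(model, tiles)
        save_model(model, tmp_path / "m.npz")
        loaded = load_model(tmp_path / "m.npz")
        assert np.allclose(score_tiles(model, tiles), score_tiles(loaded, tiles))
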