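"""Multiple-choice scoring/training, permutation channel test, FDR and the
language-modeling control."""

import numpy as np
import pytest

from megdiverge.comparison import (
    OptionScores,
    bh_fdr,
    category_improvement,
    lm_loss_control,
    mc_accuracy,
    mc_loss,
    permutation_channel_test,
    score_options,
    train_mc,
)
from megdiverge.scorer import ToyScorer
from megdiverge.simulate import (
    MCItem,
    SimConfig,
    generate_mc_dataset,
    generate_word_stream,
)

VOCAB = [f"tok{i:04d}" for i in range(200)] + ["kw_storm"]


class FixedLogitScorer:
    """Logits read from a fixed table: position-independent per-token logit
    plus a per-position offset (hand-computable oracle scaffold)."""

    def __init__(self, vocab, per_token, per_position=None):
        self.vocab = list(vocab)
        self.index = {t: i for i, t in enumerate(self.vocab)}
        self.per_token = np.asarray(per_token, dtype=float)
        self.per_position = per_position

    def encode(self, tokens):
        return np.array([self.index[t] for t in tokens], dtype=int)

    def token_logits(self, tokens):
        out = np.tile(self.per_token, (len(tokens), 1))
        if self.per_position is not None:
            out = out + np.asarray(self.per_position[: len(tokens)])[:, None]
        return out


class TestScoreOptions:
    def test_all_zero_logits_give_zero_scores(self):
        s = FixedLogitScorer(["a", "b", "c"], np.zeros(3))
        item = MCItem(context=("a",), options=(("b",), ("c", "b")), correct_index=0)
        out = score_options(s, item)
        np.testing.assert_array_equal(out.scores, [0.0, 0.0])

    def test_hand_computed_sums(self):
        # logits: a=1, b=2, c=3; positions add offsets 10, 20, 30, 40
        s = FixedLogitScorer(
            ["a", "b", "c"], [1.0, 2.0, 3.0], per_position=[10, 20, 30, 40]
        )
        item = MCItem(
            context=("a",), options=(("b",), ("c", "b", "a")), correct_index=1
        )
        out = score_options(s, item)
        # option 0: position 1 -> 2 + 20 = 22
        # option 1: positions 1,2,3 -> (3+20) + (2+30) + (1+40) = 96
        np.testing.assert_allclose(out.scores, [22.0, 96.0])
        assert out.correct_index == 1

    def test_duplicate_options_identical_scores(self):
        s = ToyScorer(VOCAB, copy_weight=0.7)
        item = MCItem(
            context=("tok0001", "tok0002"),
            options=(("tok0001",), ("tok0001",), ("tok0003",)),
            correct_index=0,
        )
        out = score_options(s, item)
        assert out.scores[0] == out.scores[1]

    def test_matches_brute_force_token_sum(self):
        s = ToyScorer(VOCAB, copy_weight=0.3,
                      bias=np.linspace(-1, 1, len(VOCAB)))
        item = generate_mc_dataset(1, 3, seed=9)[0]
        out = score_options(s, item)
        for j, opt in enumerate(item.options):
            seq = list(item.context) + list(opt)
            logits = s.token_logits(seq)
            expected = sum(
                logits[p, s.index[seq[p]]]
                for p in range(len(item.context), len(seq))
            )
            assert out.scores[j] == pytest.approx(expected, abs=1e-12)

    def test_log_softmax_variant_differs_but_ranks_same_when_uniform(self):
        s = ToyScorer(VOCAB, copy_weight=1.0)
        item = generate_mc_dataset(1, 2, seed=3)[0]
        raw = score_options(s, item, use_log_softmax=False)
        norm = score_options(s, item, use_log_softmax=True)
        assert not np.allclose(raw.scores, norm.scores)


class TestMCLoss:
    def test_uniform_scores_ln_n(self):
        out = OptionScores(scores=np.zeros(3), correct_index=1)
        assert mc_loss(out) == pytest.approx(np.log(3), abs=1e-12)

    def test_dominant_correct_score_loss_to_zero(self):
        out = OptionScores(scores=np.array([100.0, 0.0]), correct_index=0)
        assert mc_loss(out) < 1e-10

    def test_matches_logsumexp_oracle(self, rng):
        for _ in range(30):
            s = rng.standard_normal(int(rng.integers(2, 6))) * 5
            c = int(rng.integers(0, len(s)))
            got = mc_loss(OptionScores(scores=s, correct_index=c))
            # independent high-precision route: direct log-sum-exp identity
            m = s.max()
            expected = -(s[c] - m - np.log(np.exp(s - m).sum()))
            assert got == pytest.approx(expected, abs=1e-10)


class TestTrainMC:
    def test_zero_epochs_leaves_scorer_unchanged(self):
        items = generate_mc_dataset(40, 3, seed=1)
        s = ToyScorer(VOCAB)
        acc0 = mc_accuracy(s, items)
        train_mc(s, items, epochs=0, seed=0)
        assert s.copy_weight == 0.0
        assert np.all(s.bias == 0.0)
        assert mc_accuracy(s, items) == acc0

    def test_learns_separable_planted_task(self):
        items = generate_mc_dataset(300, 3, seed=2)
        train, held = items[:225], items[225:]
        s = ToyScorer(VOCAB)
        train_mc(s, train, epochs=30, lr=0.5, seed=0)
        assert mc_accuracy(s, held) >= 0.95
        assert s.copy_weight > 0  # the planted rule is "copy from context"

    def test_loss_nonincreasing_early(self):
        items = generate_mc_dataset(100, 3, seed=3)
        s = ToyScorer(VOCAB)
        train_mc(s, items, epochs=10, lr=0.1, seed=0)
        curve = s.loss_curve
        assert all(b <= a + 1e-9 for a, b in zip(curve, curve[1:]))

    def test_empty_items_rejected(self):
        with pytest.raises(ValueError):
            train_mc(ToyScorer(VOCAB), [], epochs=1)


class TestToyScorerLM:
    def test_uniform_scorer_loss_is_ln_vocab(self):
        s = ToyScorer(VOCAB)  # zero bias, zero copy weight -> uniform
        stream = ["tok0000", "tok0001", "tok0002"] * 10
        assert s.lm_loss(stream) == pytest.approx(np.log(len(VOCAB)), abs=1e-10)

    def test_train_lm_reduces_loss(self):
        rng = np.random.default_rng(0)
        stream = [f"tok{i:04d}" for i in rng.integers(0, 20, size=400)]
        s = ToyScorer(VOCAB)
        before = s.lm_loss(stream)
        s.train_lm(stream, epochs=30, lr=0.5)
        assert s.lm_loss(stream) < before

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError):
            ToyScorer(["a"]).token_logits(["a", "zzz"])


class TestPermutationChannelTest:
    def test_identical_models_nothing_significant(self, rng):
        M = rng.standard_normal((60, 4, 3))
        Mh = rng.standard_normal((60, 4, 3))
        comp = permutation_channel_test(M, Mh, Mh.copy(), n_perm=200, seed=0)
        assert np.all(comp.delta_r == 0)
        assert np.all(comp.labels == "ns")
        frac = comp.timebin_fractions()
        np.testing.assert_allclose(
            frac[["better", "worse", "ns"]].sum(axis=1), 1.0
        )

    def test_perfect_ft_vs_noise_base_all_better(self, rng):
        M = rng.standard_normal((300, 5, 2))
        ft = M + 0.01 * rng.standard_normal(M.shape)
        base = rng.standard_normal(M.shape)
        comp = permutation_channel_test(M, base, ft, n_perm=400, seed=1)
        assert np.all(comp.labels == "better")
        assert comp.p_values.max() <= 2 / 401 + 1e-12

    def test_null_false_positive_rate_near_alpha(self):
        # both predictions pure noise: significant fraction ~ alpha
        rng = np.random.default_rng(5)
        M = rng.standard_normal((100, 50, 10))  # 500 cells
        base = rng.standard_normal(M.shape)
        ft = rng.standard_normal(M.shape)
        comp = permutation_channel_test(M, base, ft, n_perm=1000,
                                        alpha=0.05, seed=2)
        frac = float((comp.labels != "ns").mean())
        # binomial: sd = sqrt(.05*.95/500) ~ 0.01; allow ~3.5 sd
        assert abs(frac - 0.05) < 0.035

    def test_shape_mismatch_rejected(self, rng):
        M = rng.standard_normal((10, 2, 2))
        with pytest.raises(ValueError):
            permutation_channel_test(M, M, rng.standard_normal((10, 2, 3)))

    def test_deterministic_given_seed(self, rng):
        M = rng.standard_normal((40, 3, 2))
        b = rng.standard_normal(M.shape)
        f = rng.standard_normal(M.shape)
        c1 = permutation_channel_test(M, b, f, n_perm=150, seed=9)
        c2 = permutation_channel_test(M, b, f, n_perm=150, seed=9)
        np.testing.assert_array_equal(c1.p_values, c2.p_values)


class TestBHFDR:
    def test_hand_listed_vector(self):
        # step-up on (0.001, 0.01, 0.02, 0.9) at alpha 0.05:
        # sorted p(i) vs i*alpha/4 = (0.0125, 0.025, 0.0375, 0.05)
        # largest i with p(i) <= threshold is i=3 -> first three rejected
        reject, p_adj = bh_fdr(np.array([0.001, 0.01, 0.02, 0.9]), alpha=0.05)
        np.testing.assert_array_equal(reject, [True, True, True, False])

    @pytest.mark.parametrize("m", [1, 7, 23, 50])
    def test_matches_brute_force_step_up(self, m, rng):
        for _ in range(20):
            p = rng.random(m) ** 2  # skew toward small values
            reject, _ = bh_fdr(p, alpha=0.05)
            # brute-force step-up enumeration
            order = np.argsort(p)
            k_star = 0
            for i in range(1, m + 1):
                if p[order[i - 1]] <= i * 0.05 / m:
                    k_star = i
            expected = np.zeros(m, dtype=bool)
            expected[order[:k_star]] = True
            np.testing.assert_array_equal(reject, expected)


class TestCategoryImprovement:
    def _events(self, n_words, category_words):
        cfg = SimConfig(n_words=n_words, n_sentences=max(1, n_words // 5), seed=4)
        events = generate_word_stream(cfg)
        out = []
        import dataclasses

        for e in events:
            flags = set(e.category_flags)
            flags.discard("social")
            flags.discard("physical")
            if e.word_id in category_words:
                flags.add("social")
            out.append(dataclasses.replace(e, category_flags=frozenset(flags)))
        return out

    def test_identical_models_nothing_significant(self, rng):
        events = self._events(50, set(range(10)))
        mse = rng.random((50, 6))
        report = category_improvement(mse, mse.copy(), events, "social")
        assert np.all(report["mean_in"] == 0)
        assert not report["significant"].any()

    def test_planted_bins_flagged_exactly(self, rng):
        # improvement injected for in-category words only, in bins 2-3
        events = self._events(400, set(range(150)))
        base = 1.0 + 0.1 * rng.random((400, 6))
        ft = base.copy()
        ft[:150, 2:4] -= 0.5  # strong in-category improvement, >> noise sd
        report = category_improvement(base, ft, events, "social", alpha=0.05)
        assert list(report.loc[report["significant"], "timebin"]) == [2, 3]
        assert (report.loc[report["significant"], "mean_in"] > 0).all()

    def test_vector_input_treated_as_single_bin(self, rng):
        events = self._events(30, set(range(10)))
        base = rng.random(30)
        report = category_improvement(base, base * 0.5, events, "social")
        assert len(report) == 1

    def test_nan_bins_excluded(self, rng):
        events = self._events(40, set(range(15)))
        base = rng.random((40, 3))
        ft = base - 0.2
        base[:, 1] = np.nan
        ft[:, 1] = np.nan
        report = category_improvement(base, ft, events, "social")
        assert np.isnan(report.loc[1, "p"])
        assert not report.loc[1, "significant"]

    def test_sparse_category_rejected(self, rng):
        events = self._events(20, {0})
        with pytest.raises(ValueError):
            category_improvement(rng.random(20), rng.random(20), events, "social")


class TestLMLossControl:
    def test_identical_scorers_zero_difference(self):
        rng = np.random.default_rng(2)
        stream = [f"tok{i:04d}" for i in rng.integers(0, 50, size=300)]
        s = ToyScorer(VOCAB, copy_weight=0.2)
        out = lm_loss_control(s, s.clone(), stream, folds=3, epochs=5)
        np.testing.assert_allclose(out["difference"], 0.0, atol=1e-12)

    def test_uniform_scorer_untrained_loss_ln_v(self):
        stream = ["tok0000"] * 30
        out = lm_loss_control(
            ToyScorer(VOCAB), ToyScorer(VOCAB), stream, folds=3, epochs=0
        )
        np.testing.assert_allclose(
            out["loss_base"], np.log(len(VOCAB)), atol=1e-10
        )

    def test_different_inits_converge_to_similar_loss(self):
        # ample text + convergent training: starting points wash out
        rng = np.random.default_rng(3)
        stream = [f"tok{i:04d}" for i in rng.integers(0, 10, size=1200)]
        a = ToyScorer(VOCAB)
        b = ToyScorer(VOCAB, copy_weight=0.3)
        out = lm_loss_control(a, b, stream, folds=3, epochs=150, lr=2.0)
        assert abs(out.iloc[-1]["difference"]) < 0.05

    def test_short_stream_rejected(self):
        with pytest.raises(ValueError):
            lm_loss_control(ToyScorer(VOCAB), ToyScorer(VOCAB), ["tok0000"],
                            folds=3)
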