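import numpy as np
import pytest

import promtok as pt
from promtok.modeling import (
    CurriculumSchedule,
    EncoderConfig,
    MaskedLanguageModel,
    PromoterClassifier,
    TrainConfig,
    ablation_curve,
    make_schedule,
    tokenize_windows,
)
from promtok.nn import init_params
from promtok.tokenizers import Vocabulary, build_kmer_vocab

TINY = EncoderConfig(layers=1, hidden=16, heads=2, max_tokens=64)


def _window(wid, seq, label, organism="reference"):
    return pt.PromoterWindow(
        id=wid, organism=organism, sequence=seq, label=label,
        source="epd_like" if label == "positive" else "fragment_negative",
        paired_positive_id=None if label == "positive" else f"{wid}_pair",
    )


def _random_windows(rng, n, label, L=60, organism="reference", prefix=""):
    return [
        _window(
            f"{prefix}{organism}_{label}{i}",
            "".join(rng.choice(list("ACGT"), size=L)),
            label,
            organism,
        )
        for i in range(n)
    ]


class TestSchedules:
    def test_flat_uses_all_organisms_every_epoch(self, epd8):
        s = make_schedule("flat", epd8.organisms, epochs=10)
        assert s.epochs == 10
        assert all(set(e) == set(epd8.organisms) for e in s.epoch_organisms)

    def test_evolutionary_restricts_late_epochs_to_nearest_four(self, epd8):
        s = make_schedule(
            "evolutionary", epd8.organisms, epd8, "reference", epochs=10,
            switch_epoch=5,
        )
        for e in s.epoch_organisms[:5]:
            assert set(e) == set(epd8.organisms)
        for e in s.epoch_organisms[5:]:
            assert set(e) == {
                "reference", "mulatta_like", "mouse_like", "rat_like"
            }

    def test_switch_at_end_degenerates_to_flat(self, epd8):
        evo = make_schedule(
            "evolutionary", epd8.organisms, epd8, "reference", epochs=6,
            switch_epoch=6,
        )
        flat = make_schedule("flat", epd8.organisms, epochs=6)
        assert evo.epoch_organisms == flat.epoch_organisms

    def test_zero_epochs_rejected(self, epd8):
        with pytest.raises(ValueError):
            make_schedule("flat", epd8.organisms, epochs=0)

    def test_empty_epoch_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CurriculumSchedule([["reference"], []])


class TestMaskedLanguageModel:
    def _corpora(self, rng, organisms, n_per=4, L=60):
        vocab = build_kmer_vocab([], 3)
        return {
            org: tokenize_windows(
                _random_windows(rng, n_per, "positive", L, org),
                "kmer_nonoverlap", vocab,
            )
            for org in organisms
        }, vocab

    def test_negative_windows_rejected_from_pretraining(self):
        rng = np.random.default_rng(0)
        vocab = build_kmer_vocab([], 3)
        seqs = tokenize_windows(
            _random_windows(rng, 2, "negative"), "kmer_nonoverlap", vocab
        )
        with pytest.raises(ValueError, match="non-positive"):
            MaskedLanguageModel({"reference": seqs}, vocab, TINY)

    def test_masked_fraction_tracks_configured_rate(self):
        rng = np.random.default_rng(1)
        corpora, vocab = self._corpora(rng, ["reference"], n_per=120, L=90)
        res = MaskedLanguageModel(corpora, vocab, TINY).fit(
            TrainConfig(epochs=2, seed=1)
        )
        for frac in res.masked_fraction:
            assert abs(frac - 0.15) < 0.01

    def test_curriculum_batches_never_leak_excluded_organisms(self, epd8):
        rng = np.random.default_rng(2)
        corpora, vocab = self._corpora(rng, epd8.organisms)
        schedule = make_schedule(
            "evolutionary", epd8.organisms, epd8, "reference", epochs=4,
            switch_epoch=2,
        )
        res = MaskedLanguageModel(corpora, vocab, TINY, schedule).fit(
            TrainConfig(epochs=4, seed=2)
        )
        near = {"reference", "mulatta_like", "mouse_like", "rat_like"}
        assert res.batch_log
        for entry in res.batch_log:
            if entry["epoch"] > 2:
                assert set(entry["organisms"]) <= near

    def test_identical_seed_gives_identical_loss_trace(self):
        rng = np.random.default_rng(3)
        corpora, vocab = self._corpora(rng, ["reference"], n_per=10)
        a = MaskedLanguageModel(corpora, vocab, TINY).fit(TrainConfig(epochs=3, seed=7))
        b = MaskedLanguageModel(corpora, vocab, TINY).fit(TrainConfig(epochs=3, seed=7))
        assert a.epoch_losses == b.epoch_losses

    def test_loss_decreases_on_structured_corpus(self):
        rng = np.random.default_rng(4)
        wins = [
            _window(f"p{i}", "ACGTTGCAT" * 7, "positive") for i in range(16)
        ]
        vocab = build_kmer_vocab([], 3)
        corpora = {"reference": tokenize_windows(wins, "kmer_nonoverlap", vocab)}
        res = MaskedLanguageModel(corpora, vocab, TINY).fit(
            TrainConfig(epochs=5, seed=4)
        )
        assert res.epoch_losses[-1] < res.epoch_losses[0]


class TestClassifier:
    def _separable(self, rng, n, L=40):
        """Positives carry a reserved 'X' token; negatives never do."""
        wins = []
        for i in range(n):
            seq = list(rng.choice(list("ACGT"), size=L))
            if i % 2 == 0:
                seq[int(rng.integers(5, L - 5))] = "X"
            wins.append(
                _window(f"s{i}", "".join(seq), "positive" if i % 2 == 0 else "negative")
            )
        return wins

    @pytest.fixture(scope="class")
    def separable_fit(self):
        rng = np.random.default_rng(5)
        vocab = Vocabulary(["A", "C", "G", "T", "X"], "char")
        enc = EncoderConfig(layers=1, hidden=32, heads=2, max_tokens=64)
        train = tokenize_windows(self._separable(rng, 64), "char", vocab)
        val = tokenize_windows(self._separable(rng, 16), "char", vocab)
        test = tokenize_windows(self._separable(rng, 16), "char", vocab)
        res = PromoterClassifier(train, val, vocab, enc).fit(
            TrainConfig(epochs=20, seed=5, learning_rate=3e-3, patience=20)
        )
        return res, test

    def test_separable_toy_reaches_perfect_auc(self, separable_fit):
        res, test = separable_fit
        scores, y, _ = res.predict(test).arrays()
        assert pt.auc(scores, y) == 1.0

    def test_probabilities_within_unit_interval(self, separable_fit):
        res, test = separable_fit
        probs = res.predict_proba(test)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_batch_size_does_not_change_predictions(self, separable_fit):
        res, test = separable_fit
        p1 = res.predict_proba(test, batch_size=1)
        p8 = res.predict_proba(test, batch_size=8)
        assert np.allclose(p1, p8, atol=1e-5)

    def test_untrained_model_sits_near_half(self):
        rng = np.random.default_rng(6)
        vocab = Vocabulary(["A", "C", "G", "T", "X"], "char")
        from promtok.modeling import ClassifierResults

        res = ClassifierResults(
            params=init_params(TINY, len(vocab), np.random.default_rng(0)),
            encoder_config=TINY, vocab=vocab,
            train_config=TrainConfig(), train_curve=[], val_curve=[0.7],
            best_epoch=-1, pretrained=False,
        )
        test = tokenize_windows(self._separable(rng, 20), "char", vocab)
        probs = res.predict_proba(test)
        assert abs(float(probs.mean()) - 0.5) < 0.2

    def test_single_class_training_data_rejected(self):
        rng = np.random.default_rng(7)
        vocab = Vocabulary(["A", "C", "G", "T"], "char")
        pos_only = tokenize_windows(
            _random_windows(rng, 4, "positive", 20), "char", vocab
        )
        with pytest.raises(ValueError, match="both classes"):
            PromoterClassifier(pos_only, pos_only, vocab, TINY)

    def test_fixed_seed_reproduces_validation_curve(self):
        rng = np.random.default_rng(8)
        vocab = Vocabulary(["A", "C", "G", "T", "X"], "char")
        train = tokenize_windows(self._separable(rng, 16), "char", vocab)
        val = tokenize_windows(self._separable(rng, 8), "char", vocab)
        a = PromoterClassifier(train, val, vocab, TINY).fit(TrainConfig(epochs=4, seed=9))
        b = PromoterClassifier(train, val, vocab, TINY).fit(TrainConfig(epochs=4, seed=9))
        assert a.val_curve == b.val_curve
        assert a.train_curve == b.train_curve


GRAMMAR = "ACGTTGCAT"


def _grammar_window(rng, wid, label, L=90):
    """Positive: phase-randomized periodic grammar with 5% noise.
    Negative: the same sequence with its 3-mer blocks shuffled — identical
    token multiset, order destroyed."""
    phase = int(rng.integers(len(GRAMMAR)))
    s = list((GRAMMAR * 13)[phase : phase + L])
    for j in np.flatnonzero(rng.random(L) < 0.05):
        s[j] = "ACGT"[rng.integers(4)]
    seq = "".join(s)
    if label == "negative":
        blocks = [seq[i : i + 3] for i in range(0, L, 3)]
        seq = "".join(rng.permutation(blocks))
    return _window(wid, seq, label)


class TestPretrainingTransfer:
    def test_pretrained_beats_scratch_on_order_dominated_task(self):
        """Masked-LM pretraining on coherent positives should transfer to a
        classification task where the classes share token composition and
        differ only in token order — information a small model cannot
        extract from a few dozen labeled examples alone."""
        enc_cfg = EncoderConfig(layers=1, hidden=32, heads=2, max_tokens=40)
        vocab = build_kmer_vocab([], 3)
        wins = {"pre": 0, "scratch": 0}
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            pre = [
                _grammar_window(rng, f"pre{i}", "positive") for i in range(300)
            ]
            corpora = {
                "reference": tokenize_windows(pre, "kmer_nonoverlap", vocab)
            }
            mlm = MaskedLanguageModel(corpora, vocab, enc_cfg).fit(
                TrainConfig(epochs=15, seed=seed)
            )
            tr = [
                _grammar_window(rng, f"t{i}", "positive" if i % 2 == 0 else "negative")
                for i in range(60)
            ]
            va = [
                _grammar_window(rng, f"v{i}", "positive" if i % 2 == 0 else "negative")
                for i in range(30)
            ]
            trs = tokenize_windows(tr, "kmer_nonoverlap", vocab)
            vas = tokenize_windows(va, "kmer_nonoverlap", vocab)
            cfg = TrainConfig(epochs=20, seed=seed, patience=20)
            warm = PromoterClassifier(
                trs, vas, vocab, enc_cfg, pretrained=mlm.params
            ).fit(cfg)
            cold = PromoterClassifier(trs, vas, vocab, enc_cfg).fit(cfg)
            if np.mean(warm.val_curve) < np.mean(cold.val_curve):
                wins["pre"] += 1
            else:
                wins["scratch"] += 1
        assert wins["pre"] > wins["scratch"]


class TestAblationCurve:
    def test_table_structure_and_auc_range(self):
        rng = np.random.default_rng(10)
        vocab = Vocabulary(["A", "C", "G", "T", "X"], "char")

        def labeled(n, prefix):
            out = []
            for i in range(n):
                seq = list(rng.choice(list("ACGT"), size=30))
                label = "positive" if i % 2 == 0 else "negative"
                if label == "positive":
                    seq[10] = "X"
                out.append(_window(f"{prefix}{i}", "".join(seq), label))
            return out

        pool = tokenize_windows(labeled(40, "pool"), "char", vocab)
        test = tokenize_windows(labeled(16, "test"), "char", vocab)
        state = init_params(TINY, len(vocab), np.random.default_rng(1))
        table = ablation_curve(
            {"flat": state}, pool, [8, 16], test, vocab, TINY,
            TrainConfig(epochs=3, seed=0), replicates=2,
        )
        assert len(table) == 1 * 2 * 2  # strategies x sizes x replicates
        assert set(table.columns) == {"strategy", "n", "replicate", "auc"}
        assert table["auc"].between(0, 1).all()

    def test_odd_sizes_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ablation_curve({}, [], [7], [], None)
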