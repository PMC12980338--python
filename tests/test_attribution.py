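import numpy as np
import pytest

import promtok as pt
from promtok.attribution import (
    PositionalProfile,
    TokenAttribution,
    composition_at_position,
    peak_report,
    positional_profile,
    select_top_confident,
    token_attribution,
    top_tokens,
)
from promtok.modeling import (
    ClassifierResults,
    EncoderConfig,
    PredictionSet,
    TrainConfig,
    tokenize_windows,
)
from promtok.nn import init_params
from promtok.tokenizers import Vocabulary, build_kmer_vocab, encode


class _StubResults(ClassifierResults):
    """ClassifierResults whose probability is a pure function of the ids."""

    def __init__(self, vocab, fn):
        self.vocab = vocab
        self._fn = fn

    def predict_proba(self, seqs, batch_size=8):  # unused by attribution
        raise NotImplementedError


def _make_stub(vocab, fn):
    """Build a stub by monkeypatching the probe over raw id rows."""
    import promtok.attribution as attr

    stub = ClassifierResults(
        params=init_params(
            EncoderConfig(layers=1, hidden=16, heads=2, max_tokens=64),
            len(vocab),
            np.random.default_rng(0),
        ),
        encoder_config=EncoderConfig(layers=1, hidden=16, heads=2, max_tokens=64),
        vocab=vocab,
        train_config=TrainConfig(),
        train_curve=[], val_curve=[0.7], best_epoch=-1, pretrained=False,
    )
    return stub, fn


@pytest.fixture()
def char_vocab():
    return Vocabulary(["A", "C", "G", "T", "X"], "char")


def _probe_patch(monkeypatch, fn):
    import promtok.attribution as attr

    monkeypatch.setattr(attr, "_probe", lambda results, rows: fn(rows))


class TestSelectTopConfident:
    def _preds(self, probs, labels):
        return PredictionSet(probabilities=probs, labels=labels)

    def test_positives_ranked_by_probability_descending(self):
        preds = self._preds(
            {"a": 0.2, "b": 0.9, "c": 0.5},
            {"a": "positive", "b": "positive", "c": "positive"},
        )
        assert select_top_confident(preds, "positive", 2) == ["b", "c"]

    def test_negatives_ranked_ascending(self):
        preds = self._preds(
            {"a": 0.2, "b": 0.9, "c": 0.5},
            {k: "negative" for k in "abc"},
        )
        assert select_top_confident(preds, "negative", 2) == ["a", "c"]

    def test_shortfall_returns_all_with_warning(self):
        preds = self._preds({"a": 0.9}, {"a": "positive"})
        with pytest.warns(UserWarning, match="only 1"):
            out = select_top_confident(preds, "positive", 100)
        assert out == ["a"]

    def test_probability_tie_broken_by_id(self):
        preds = self._preds(
            {"z": 0.5, "a": 0.5, "m": 0.5},
            {k: "positive" for k in "zam"},
        )
        assert select_top_confident(preds, "positive", 2) == ["a", "m"]

    def test_empty_class_rejected(self):
        preds = self._preds({"a": 0.5}, {"a": "positive"})
        with pytest.raises(ValueError, match="negative"):
            select_top_confident(preds, "negative", 5)


class TestTokenAttribution:
    def test_constant_model_gives_zero_occlusion_scores(
        self, monkeypatch, char_vocab
    ):
        _probe_patch(monkeypatch, lambda rows: np.full(len(rows), 0.75))
        stub, _ = _make_stub(char_vocab, None)
        seq = encode("ACGTAC", "char", char_vocab, window_id="w")
        att = token_attribution(stub, seq, "occlusion")
        assert np.allclose(att.scores, 0.0)

    def test_decisive_token_dominates_occlusion(self, monkeypatch, char_vocab):
        x_id = char_vocab.id_of("X")

        def fn(rows):
            return np.where((rows == x_id).any(axis=1), 0.95, 0.05)

        _probe_patch(monkeypatch, fn)
        stub, _ = _make_stub(char_vocab, None)
        seq = encode("ACXTAC", "char", char_vocab, window_id="w")
        att = token_attribution(stub, seq, "occlusion")
        assert int(np.argmax(np.abs(att.scores))) == 2
        assert att.scores[2] == pytest.approx(0.9)

    def test_occlusion_scores_bounded_by_probability_range(
        self, monkeypatch, char_vocab
    ):
        rng = np.random.default_rng(1)
        _probe_patch(monkeypatch, lambda rows: rng.random(len(rows)))
        stub, _ = _make_stub(char_vocab, None)
        seq = encode("ACGT" * 5, "char", char_vocab, window_id="w")
        att = token_attribution(stub, seq, "occlusion")
        assert np.all(np.abs(att.scores) <= 1.0)

    def test_shapley_and_occlusion_agree_on_decisive_token(
        self, monkeypatch, char_vocab
    ):
        x_id = char_vocab.id_of("X")

        def fn(rows):
            return np.where((rows == x_id).any(axis=1), 0.95, 0.05)

        _probe_patch(monkeypatch, fn)
        stub, _ = _make_stub(char_vocab, None)
        seq = encode("ACXTAC", "char", char_vocab, window_id="w")
        occ = token_attribution(stub, seq, "occlusion")
        shap = token_attribution(stub, seq, "shapley", n_samples=20, seed=0)
        assert int(np.argmax(shap.scores)) == int(np.argmax(occ.scores)) == 2

    def test_unknown_method_rejected(self, char_vocab):
        stub, _ = _make_stub(char_vocab, None)
        seq = encode("ACGT", "char", char_vocab)
        with pytest.raises(ValueError, match="method"):
            token_attribution(stub, seq, "integrated-gradients")

    def test_real_model_occlusion_runs_end_to_end(self):
        # no stubs: a real (untrained) encoder, scores finite and bounded
        vocab = build_kmer_vocab([], 3)
        enc = EncoderConfig(layers=1, hidden=16, heads=2, max_tokens=16)
        res = ClassifierResults(
            params=init_params(enc, len(vocab), np.random.default_rng(2)),
            encoder_config=enc, vocab=vocab, train_config=TrainConfig(),
            train_curve=[], val_curve=[0.7], best_epoch=-1, pretrained=False,
        )
        seq = encode("ACGTACGTACGTACGTACGTACGTACGTAC", "kmer_nonoverlap", vocab)
        att = token_attribution(res, seq, "occlusion")
        assert len(att.scores) == 10
        assert np.all(np.isfinite(att.scores))


def _att(scores, seq):
    return TokenAttribution(np.asarray(scores, dtype=float), seq, "occlusion")


class TestPositionalProfile:
    def test_nonoverlap_token_score_broadcast_to_its_six_positions(
        self, tiny_vocab
    ):
        seq = encode("A" * 601, "kmer_nonoverlap", tiny_vocab, window_id="w")
        scores = np.arange(100, dtype=float)
        prof = positional_profile([_att(scores, seq)])
        assert np.all(prof.values[0:6] == 0.0)
        assert np.all(prof.values[6:12] == 1.0)
        assert np.isnan(prof.values[600])  # uncovered tail

    def test_uniform_scores_give_flat_profile(self, tiny_vocab):
        seq = encode("C" * 601, "kmer_nonoverlap", tiny_vocab, window_id="w")
        prof = positional_profile([_att(np.full(100, 0.3), seq)])
        assert np.allclose(prof.values[:600], 0.3)

    def test_overlap_positions_average_covering_tokens(self):
        vocab = build_kmer_vocab([], 3, overlapping=True)
        seq = encode("ACGTACG", "kmer_overlap", vocab, window_id="w")
        scores = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        prof = positional_profile([_att(scores, seq)], length=7)
        # brute-force oracle: per-position mean over covering spans
        oracle = np.zeros(7)
        count = np.zeros(7)
        for s, (a, b) in zip(scores, seq.spans):
            oracle[a:b] += s
            count[a:b] += 1
        oracle /= count
        assert np.allclose(prof.values, oracle)

    def test_profile_equals_mean_of_per_window_vectors(self, tiny_vocab):
        rng = np.random.default_rng(3)
        seqs = [
            encode("G" * 601, "kmer_nonoverlap", tiny_vocab, window_id=f"w{i}")
            for i in range(5)
        ]
        atts = [_att(rng.normal(size=100), s) for s in seqs]
        prof = positional_profile(atts)
        per_window = []
        for a in atts:
            v = np.full(601, np.nan)
            for s, (lo, hi) in zip(a.scores, a.sequence.spans):
                v[lo:hi] = s
            per_window.append(v)
        oracle = np.nanmean(np.stack(per_window), axis=0)
        assert np.allclose(prof.values[:600], oracle[:600])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            positional_profile([])


class TestPeakReport:
    def test_peak_at_index_390_reports_offset_plus_90(self):
        vals = np.zeros(601)
        vals[390] = 1.0
        rep = peak_report(PositionalProfile(vals, 1), top_k=1)
        assert rep[0]["index"] == 390
        assert rep[0]["offset"] == 90

    def test_constant_profile_flagged_degenerate(self):
        rep = peak_report(PositionalProfile(np.full(601, 0.5), 1), top_k=3)
        assert all(r["degenerate"] for r in rep)
        assert [r["index"] for r in rep] == [0, 1, 2]

    def test_nan_tail_ignored(self):
        vals = np.full(601, 0.1)
        vals[600] = np.nan
        vals[123] = 0.9
        rep = peak_report(PositionalProfile(vals, 1), top_k=1)
        assert rep[0]["index"] == 123


class TestComposition:
    def test_frequencies_sum_to_one(self, small_windows):
        freqs = composition_at_position(small_windows, 390)
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_homogeneous_windows(self):
        wins = ["A" * 601] * 4
        assert composition_at_position(wins, 10)["A"] == 1.0

    def test_hand_tallied_counts(self):
        wins = ["A" * 10, "C" * 10, "C" * 10, "G" * 10, "T" * 10]
        freqs = composition_at_position(wins, 5)
        assert freqs == {"A": 0.2, "C": 0.4, "G": 0.2, "T": 0.2, "N": 0.0}

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            composition_at_position(["ACGT"], 10)


class TestTopTokens:
    def test_zero_tokens_gives_empty_reports(self, char_vocab):
        seq = encode("ACGT", "char", char_vocab, window_id="w")
        per_window, freq = top_tokens([_att([0.1] * 4, seq)], n_tokens=0)
        assert per_window == [[]]
        assert freq == {}

    def test_decisive_token_tops_every_report(self, char_vocab):
        seqs = [
            encode("ACXT", "char", char_vocab, window_id=f"w{i}") for i in range(3)
        ]
        atts = [_att([0.0, 0.1, 0.9, 0.0], s) for s in seqs]
        per_window, freq = top_tokens(atts, n_sequences=3, n_tokens=1)
        assert all(rep[0]["token"] == "X" for rep in per_window)
        assert freq == {"X": 3}

    def test_tie_ranked_by_span_start(self, char_vocab):
        seq = encode("ACGT", "char", char_vocab, window_id="w")
        per_window, _ = top_tokens([_att([0.5, 0.5, 0.5, 0.5], seq)], n_tokens=2)
        assert [r["span"] for r in per_window[0]] == [(0, 1), (1, 2)]
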