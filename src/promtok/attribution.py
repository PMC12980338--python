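"""Positional attribution: which parts of a promoter window drive the
classifier.

The procedure mirrors the explainability analysis the pipeline is built
around: take the test sequences the classifier is most confident about
(top 100 positives by predicted promoter probability; as a negative
control, the 100 negatives it is most confident about), attribute the
prediction to individual tokens, broadcast each token's score onto the
nucleotide positions it covers, and average per position across the
selected sequences.  The result is a length-601 profile indexed by
TSS-relative offset (-300..+300; window index ``i`` maps to offset
``i - 300``), in which, e.g., a planted downstream element near +90 should
appear as a peak around index 390.

Two attribution methods are provided on the promoter-probability scale:

* ``occlusion`` — score of token t is ``P(promoter|x) - P(promoter|x with
  t replaced by [MASK])``; bounded in [-1, 1], dependency-free, the
  default.
* ``shapley`` — Monte-Carlo permutation estimate of Shapley values with
  the [MASK] token as the background: for sampled orderings, tokens are
  revealed one at a time and the marginal change in predicted probability
  is credited to the revealed token.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .modeling import ClassifierResults, PredictionSet, _pad_batch
from .tokenizers import TokenizedSequence

__all__ = [
    "TokenAttribution",
    "PositionalProfile",
    "select_top_confident",
    "token_attribution",
    "positional_profile",
    "peak_report",
    "composition_at_position",
    "top_tokens",
]


@dataclass
class TokenAttribution:
    """Per-token scores aligned with a tokenized window."""

    scores: np.ndarray
    sequence: TokenizedSequence
    method: str

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.sequence):
            raise ValueError("one score per content token required")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("attribution scores must be finite")


@dataclass
class PositionalProfile:
    """Mean attribution per window position (NaN at uncovered positions)."""

    values: np.ndarray
    n_sequences: int
    class_tag: str = "positive"

    @property
    def length(self) -> int:
        return len(self.values)

    def offset(self, index: int) -> int:
        return index - (self.length - 1) // 2


def select_top_confident(
    preds: PredictionSet, target_class: str, n: int = 100
) -> list[str]:
    """Ids of the ``n`` most confidently classified records of a class.

    Positives rank by probability descending, negatives ascending; ties
    break by id ascending.  If fewer than ``n`` are available all are
    returned with a warning.
    """
    if target_class not in ("positive", "negative"):
        raise ValueError(f"bad target class {target_class!r}")
    ids = [i for i, lab in preds.labels.items() if lab == target_class]
    if not ids:
        raise ValueError(f"no records of class {target_class!r}")
    sign = -1.0 if target_class == "positive" else 1.0
    ranked = sorted(ids, key=lambda i: (sign * preds.probabilities[i], i))
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} {target_class} records available "
            f"(requested {n})",
            stacklevel=2,
        )
    return ranked[:n]


def _probe(results: ClassifierResults, ids_batch: np.ndarray) -> np.ndarray:
    """Promoter probabilities for a batch of raw id rows (CLS included)."""
    enc = results._encoder()
    mask = np.ones_like(ids_batch, dtype=bool)
    hidden, _ = enc.forward(results.params, ids_batch, mask)
    return enc.cls_forward(results.params, hidden)


def token_attribution(
    results: ClassifierResults,
    seq: TokenizedSequence,
    method: str = "occlusion",
    n_samples: int = 30,
    seed: int = 0,
    batch_size: int = 64,
) -> TokenAttribution:
    """Attribute the promoter probability of one window to its tokens."""
    if method not in ("occlusion", "shapley"):
        raise ValueError(f"unknown attribution method {method!r}")
    vocab = results.vocab
    n_tok = len(seq)
    base_row = np.concatenate(([vocab.cls_id], seq.ids)).astype(np.int64)
    if method == "occlusion":
        rows = [base_row]
        for t in range(n_tok):
            row = base_row.copy()
            row[1 + t] = vocab.mask_id
            rows.append(row)
        probs = np.empty(len(rows))
        rows_arr = np.stack(rows)
        for s in range(0, len(rows), batch_size):
            probs[s : s + batch_size] = _probe(results, rows_arr[s : s + batch_size])
        scores = probs[0] - probs[1:]
        return TokenAttribution(scores, seq, "occlusion")
    # Monte-Carlo permutation Shapley, [MASK] background
    rng = np.random.default_rng(seed)
    masked_row = base_row.copy()
    masked_row[1:] = vocab.mask_id
    contrib = np.zeros(n_tok)
    for _ in range(n_samples):
        order = rng.permutation(n_tok)
        rows = np.tile(masked_row, (n_tok + 1, 1))
        for step, t in enumerate(order):
            rows[step + 1 :, 1 + t] = base_row[1 + t]
        probs = np.empty(n_tok + 1)
        for s in range(0, n_tok + 1, batch_size):
            probs[s : s + batch_size] = _probe(results, rows[s : s + batch_size])
        contrib[order] += np.diff(probs)
    return TokenAttribution(contrib / n_samples, seq, "shapley")


def _per_window_positional(att: TokenAttribution, length: int) -> np.ndarray:
    """Broadcast token scores to positions: each position carries the mean
    score of the tokens covering it; NaN where nothing covers."""
    total = np.zeros(length)
    count = np.zeros(length)
    for score, (a, b) in zip(att.scores, att.sequence.spans):
        if a < 0 or b > length:
            raise ValueError(f"span ({a}, {b}) outside [0, {length})")
        total[a:b] += score
        count[a:b] += 1.0
    with np.errstate(invalid="ignore"):
        vals = total / count
    vals[count == 0] = np.nan
    return vals


def positional_profile(
    attributions: list[TokenAttribution],
    length: int = 601,
    class_tag: str = "positive",
) -> PositionalProfile:
    """Mean per-position attribution over the selected windows.

    Token scores are duplicated across the nucleotides each token covers
    (mean when several tokens cover a position, as under overlapping
    k-mers); positions no token covers — e.g. the dropped non-overlapping
    k-mer tail — stay NaN and are excluded from averaging.
    """
    if not attributions:
        raise ValueError("no attributions supplied")
    mat = np.stack([_per_window_positional(a, length) for a in attributions])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(mat, axis=0)
    return PositionalProfile(values, len(attributions), class_tag)


def peak_report(
    profile: PositionalProfile, top_k: int = 5
) -> list[dict]:
    """The ``top_k`` highest-attribution positions with TSS-relative offsets.

    A constant profile is flagged degenerate (its ordering is meaningless).
    """
    vals = profile.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("profile has no finite values")
    degenerate = bool(np.nanmax(vals) - np.nanmin(vals) < 1e-12)
    order = np.argsort(np.where(finite, -vals, np.inf), kind="stable")[:top_k]
    return [
        {
            "index": int(i),
            "offset": profile.offset(int(i)),
            "value": float(vals[i]),
            "degenerate": degenerate,
        }
        for i in order
    ]


def composition_at_position(windows, index: int) -> dict[str, float]:
    """A/C/G/T/N frequencies at one window index across windows."""
    seqs = [w.sequence if hasattr(w, "sequence") else w for w in windows]
    if not seqs:
        raise ValueError("no windows supplied")
    if index < 0 or any(index >= len(s) for s in seqs):
        raise IndexError(f"index {index} outside the windows")
    counts = {b: 0 for b in "ACGTN"}
    for s in seqs:
        counts[s[index]] += 1
    total = len(seqs)
    return {b: c / total for b, c in counts.items()}


def top_tokens(
    attributions: list[TokenAttribution],
    n_sequences: int = 5,
    n_tokens: int = 10,
) -> tuple[list[list[dict]], dict[str, int]]:
    """Highest-scoring tokens of the first ``n_sequences`` windows.

    Returns per-window ranked token reports (score desc, span start asc)
    plus an aggregate token-string frequency table across those windows.
    """
    per_window: list[list[dict]] = []
    freq: dict[str, int] = {}
    for att in attributions[:n_sequences]:
        ranked = sorted(
            range(len(att.scores)),
            key=lambda t: (-att.scores[t], att.sequence.spans[t][0]),
        )[:n_tokens]
        report = [
            {
                "token": att.sequence.tokens[t],
                "score": float(att.scores[t]),
                "span": att.sequence.spans[t],
            }
            for t in ranked
        ]
        per_window.append(report)
        for r in report:
            freq[r["token"]] = freq.get(r["token"], 0) + 1
    return per_window, freq
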