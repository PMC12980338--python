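"""DNA tokenization schemes: k-mer (overlapping / non-overlapping), BPE,
WordPiece-style (WPC), and a character-level baseline.

Every encoder returns per-token nucleotide spans so token-level attribution
scores can later be broadcast back onto individual positions.

Subword trainers start from single characters and merge adjacent pairs:
BPE merges the globally most frequent pair; WPC merges the pair maximizing
the likelihood score ``count(ab) / (count(a) * count(b))``.  Pairs with an
ambiguous base ('N') on either side are excluded from merging, so no
multi-character token ever contains 'N'.  Ties break to the
lexicographically smallest pair; merges never cross sequence boundaries.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SPECIALS",
    "Vocabulary",
    "MergeTable",
    "TokenizedSequence",
    "build_kmer_vocab",
    "build_char_vocab",
    "train_bpe",
    "train_wpc",
    "encode",
    "save_vocab",
    "load_vocab",
]

#: special tokens, in fixed id order 0..4
SPECIALS = ("[PAD]", "[UNK]", "[MASK]", "[CLS]", "[SEP]")

SCHEMES = ("kmer_nonoverlap", "kmer_overlap", "bpe", "wpc", "char")


@dataclass
class Vocabulary:
    """Ordered content tokens plus the five specials (ids 0..4)."""

    tokens: list[str]
    scheme: str
    k: int | None = None
    token_to_id: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate content tokens")
        if set(self.tokens) & set(SPECIALS):
            raise ValueError("content tokens collide with specials")
        self.token_to_id = {t: i for i, t in enumerate(SPECIALS)}
        for t in self.tokens:
            self.token_to_id[t] = len(self.token_to_id)

    def __len__(self) -> int:
        return len(SPECIALS) + len(self.tokens)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def unk_id(self) -> int:
        return 1

    @property
    def mask_id(self) -> int:
        return 2

    @property
    def cls_id(self) -> int:
        return 3

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def token_of(self, idx: int) -> str:
        if idx < len(SPECIALS):
            return SPECIALS[idx]
        return self.tokens[idx - len(SPECIALS)]


@dataclass
class MergeTable:
    """Ranked merge rules; rank = list position."""

    merges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.rank = {pair: r for r, pair in enumerate(self.merges)}

    def __len__(self) -> int:
        return len(self.merges)


@dataclass
class TokenizedSequence:
    """Token ids aligned with half-open nucleotide spans."""

    ids: np.ndarray
    tokens: list[str]
    spans: list[tuple[int, int]]
    window_id: str = ""
    uncovered: tuple[int, int] | None = None  # dropped tail, if any
    label: str | None = None
    organism: str | None = None

    def __len__(self) -> int:
        return len(self.tokens)


# ---------------------------------------------------------------------------
# vocabulary construction


def build_kmer_vocab(
    corpus: list[str], k: int = 6, overlapping: bool = False
) -> Vocabulary:
    """All ``4^k`` unambiguous k-mers plus every N-containing k-mer that the
    corpus actually produces under the chosen tokenization grid."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tokens = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    ambiguous = set()
    step = 1 if overlapping else k
    for seq in corpus:
        for i in range(0, len(seq) - k + 1, step):
            kmer = seq[i : i + k]
            if "N" in kmer:
                ambiguous.add(kmer)
    tokens.extend(sorted(ambiguous))
    return Vocabulary(tokens, "kmer_overlap" if overlapping else "kmer_nonoverlap", k)


def build_char_vocab(corpus: list[str]) -> Vocabulary:
    chars = sorted(set("ACGT") | {c for seq in corpus for c in seq})
    return Vocabulary(chars, "char", 1)


# ---------------------------------------------------------------------------
# subword trainers


class _MergeState:
    """Corpus segmentation with incrementally maintained pair statistics."""

    def __init__(self, corpus: list[str]):
        self.seqs: list[list[str]] = [list(s) for s in corpus]
        self.token_counts: Counter[str] = Counter()
        self.pair_counts: Counter[tuple[str, str]] = Counter()
        self.pair_seqs: dict[tuple[str, str], set[int]] = {}
        for si, s in enumerate(self.seqs):
            self.token_counts.update(s)
            for pair in zip(s, s[1:]):
                self.pair_counts[pair] += 1
                self.pair_seqs.setdefault(pair, set()).add(si)

    def apply_merge(self, pair: tuple[str, str]) -> None:
        merged = pair[0] + pair[1]
        for si in sorted(self.pair_seqs.get(pair, ())):
            s = self.seqs[si]
            # retract this sequence's contributions
            self.token_counts.subtract(s)
            for p in zip(s, s[1:]):
                self.pair_counts[p] -= 1
                if self.pair_counts[p] <= 0:
                    del self.pair_counts[p]
                    self.pair_seqs.pop(p, None)
            # left-to-right non-overlapping replacement
            out: list[str] = []
            i = 0
            while i < len(s):
                if i + 1 < len(s) and s[i] == pair[0] and s[i + 1] == pair[1]:
                    out.append(merged)
                    i += 2
                else:
                    out.append(s[i])
                    i += 1
            self.seqs[si] = out
            self.token_counts.update(out)
            for p in zip(out, out[1:]):
                self.pair_counts[p] += 1
                self.pair_seqs.setdefault(p, set()).add(si)
        self.token_counts += Counter()  # drop zero/negative entries


def _eligible(pair: tuple[str, str]) -> bool:
    return "N" not in pair[0] and "N" not in pair[1]


def _alphabet_size(state: _MergeState) -> int:
    return len([t for t in state.token_counts if state.token_counts[t] > 0])


def train_bpe(
    corpus: list[str], target_vocab: int, seed: int | None = None
) -> tuple[Vocabulary, MergeTable]:
    """Byte-pair-encoding trainer.

    Starts from single characters, repeatedly merges the most frequent
    eligible adjacent pair (ties: lexicographically smallest), and stops at
    ``target_vocab`` content tokens or when no pair occurs at least twice.
    Deterministic; ``seed`` is accepted for interface uniformity only.
    """
    state = _MergeState(corpus)
    alphabet = sorted(t for t in state.token_counts)
    if target_vocab < len(alphabet):
        raise ValueError(
            f"target_vocab={target_vocab} below alphabet size {len(alphabet)}"
        )
    merges: list[tuple[str, str]] = []
    content = list(alphabet)
    while len(content) < target_vocab:
        candidates = [
            (p, c) for p, c in state.pair_counts.items() if c >= 2 and _eligible(p)
        ]
        if not candidates:
            break
        best_pair, _ = min(candidates, key=lambda pc: (-pc[1], pc[0]))
        state.apply_merge(best_pair)
        merges.append(best_pair)
        content.append(best_pair[0] + best_pair[1])
    return Vocabulary(content, "bpe"), MergeTable(merges)


def train_wpc(
    corpus: list[str],
    min_pair_count: int = 2,
    target_vocab: int | None = None,
) -> tuple[Vocabulary, MergeTable]:
    """WordPiece-style trainer.

    Merges the eligible pair maximizing ``count(ab)/(count(a)*count(b))``
    each round; stops when the best pair's raw count drops below
    ``min_pair_count`` or (if given) ``target_vocab`` content tokens exist.
    """
    if min_pair_count < 2:
        raise ValueError("min_pair_count must be >= 2")
    state = _MergeState(corpus)
    alphabet = sorted(t for t in state.token_counts)
    if target_vocab is not None and target_vocab < len(alphabet):
        raise ValueError(
            f"target_vocab={target_vocab} below alphabet size {len(alphabet)}"
        )
    merges: list[tuple[str, str]] = []
    content = list(alphabet)
    while target_vocab is None or len(content) < target_vocab:
        best_pair = None
        best_key = None
        for p, c in state.pair_counts.items():
            if c < min_pair_count or not _eligible(p):
                continue
            score = c / (state.token_counts[p[0]] * state.token_counts[p[1]])
            key = (-score, p)
            if best_key is None or key < best_key:
                best_key = key
                best_pair = p
        if best_pair is None:
            break
        state.apply_merge(best_pair)
        merges.append(best_pair)
        content.append(best_pair[0] + best_pair[1])
    return Vocabulary(content, "wpc"), MergeTable(merges)


# ---------------------------------------------------------------------------
# encoding


def _encode_kmer(
    seq: str, vocab: Vocabulary, overlapping: bool
) -> tuple[list[str], list[tuple[int, int]], tuple[int, int] | None]:
    k = vocab.k
    assert k is not None
    tokens, spans = [], []
    if overlapping:
        for i in range(len(seq) - k + 1):
            tokens.append(seq[i : i + k])
            spans.append((i, i + k))
        return tokens, spans, None
    n_full = len(seq) // k
    for i in range(n_full):
        tokens.append(seq[i * k : (i + 1) * k])
        spans.append((i * k, (i + 1) * k))
    uncovered = (n_full * k, len(seq)) if n_full * k < len(seq) else None
    return tokens, spans, uncovered


def _encode_bpe(
    seq: str, merges: MergeTable
) -> tuple[list[str], list[tuple[int, int]]]:
    tokens = list(seq)
    spans = [(i, i + 1) for i in range(len(seq))]
    rank = merges.rank
    while True:
        best_i = -1
        best_rank = None
        for i in range(len(tokens) - 1):
            r = rank.get((tokens[i], tokens[i + 1]))
            if r is not None and (best_rank is None or r < best_rank):
                best_rank = r
                best_i = i
        if best_i < 0:
            break
        # apply this merge everywhere left-to-right, non-overlapping
        pair = (tokens[best_i], tokens[best_i + 1])
        out_t, out_s = [], []
        i = 0
        while i < len(tokens):
            if (
                i + 1 < len(tokens)
                and tokens[i] == pair[0]
                and tokens[i + 1] == pair[1]
            ):
                out_t.append(pair[0] + pair[1])
                out_s.append((spans[i][0], spans[i + 1][1]))
                i += 2
            else:
                out_t.append(tokens[i])
                out_s.append(spans[i])
                i += 1
        tokens, spans = out_t, out_s
    return tokens, spans


def _encode_wpc(
    seq: str, vocab: Vocabulary
) -> tuple[list[str], list[tuple[int, int]]]:
    by_len: dict[int, set[str]] = {}
    for t in vocab.tokens:
        by_len.setdefault(len(t), set()).add(t)
    max_len = max(by_len) if by_len else 1
    tokens, spans = [], []
    i = 0
    while i < len(seq):
        for L in range(min(max_len, len(seq) - i), 0, -1):
            cand = seq[i : i + L]
            if cand in by_len.get(L, ()):
                tokens.append(cand)
                spans.append((i, i + L))
                i += L
                break
        else:
            tokens.append(seq[i])  # maps to UNK below
            spans.append((i, i + 1))
            i += 1
    return tokens, spans


def encode(
    seq: str,
    scheme: str,
    vocab: Vocabulary,
    merges: MergeTable | None = None,
    window_id: str = "",
) -> TokenizedSequence:
    """Tokenize one sequence under the given scheme.

    Out-of-vocabulary content maps to ``[UNK]``; spans always cover the
    emitted tokens, and any dropped non-overlapping-k-mer tail is recorded
    in ``uncovered``.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if vocab.scheme != scheme:
        raise ValueError(f"vocabulary is for {vocab.scheme!r}, not {scheme!r}")
    uncovered = None
    if scheme in ("kmer_nonoverlap", "kmer_overlap"):
        tokens, spans, uncovered = _encode_kmer(
            seq, vocab, overlapping=scheme == "kmer_overlap"
        )
    elif scheme == "bpe":
        if merges is None:
            raise ValueError("bpe encoding requires a MergeTable")
        tokens, spans = _encode_bpe(seq, merges)
    elif scheme == "wpc":
        tokens, spans = _encode_wpc(seq, vocab)
    else:  # char
        tokens = list(seq)
        spans = [(i, i + 1) for i in range(len(seq))]
    ids = np.array([vocab.id_of(t) for t in tokens], dtype=np.int32)
    return TokenizedSequence(ids, tokens, spans, window_id, uncovered)


# ---------------------------------------------------------------------------
# persistence (plain text: one token per line; merges "left right" by rank)


def save_vocab(
    vocab: Vocabulary, merges: MergeTable | None, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# scheme={vocab.scheme} k={vocab.k if vocab.k is not None else '-'}\n"
    with open(outdir / "vocab.txt", "w") as fh:
        fh.write(header)
        for t in SPECIALS:
            fh.write(t + "\n")
        for t in vocab.tokens:
            fh.write(t + "\n")
    if merges is not None:
        with open(outdir / "merges.txt", "w") as fh:
            for left, right in merges.merges:
                fh.write(f"{left} {right}\n")


def load_vocab(outdir: str | Path) -> tuple[Vocabulary, MergeTable | None]:
    outdir = Path(outdir)
    lines = (outdir / "vocab.txt").read_text().splitlines()
    if not lines or not lines[0].startswith("# scheme="):
        raise ValueError(f"{outdir}/vocab.txt: missing scheme header")
    head = dict(kv.split("=") for kv in lines[0][2:].split())
    scheme = head["scheme"]
    k = None if head.get("k", "-") == "-" else int(head["k"])
    tokens = [ln for ln in lines[1:] if ln]
    if tokens[: len(SPECIALS)] != list(SPECIALS):
        raise ValueError(f"{outdir}/vocab.txt: specials missing or reordered")
    vocab = Vocabulary(tokens[len(SPECIALS) :], scheme, k)
    merges = None
    merges_path = outdir / "merges.txt"
    if merges_path.exists():
        pairs = []
        known = set("ACGTN") | set(vocab.tokens)
        for lineno, ln in enumerate(merges_path.read_text().splitlines(), 1):
            if not ln.strip():
                continue
            parts = ln.split(" ")
            if len(parts) != 2:
                raise ValueError(f"{merges_path}:{lineno}: malformed merge line")
            left, right = parts
            if left not in known or right not in known:
                raise ValueError(
                    f"{merges_path}:{lineno}: merge references unknown token"
                )
            if left + right not in known:
                raise ValueError(
                    f"{merges_path}:{lineno}: merged token {left + right!r} "
                    "not in vocabulary"
                )
            pairs.append((left, right))
        merges = MergeTable(pairs)
    return vocab, merges
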