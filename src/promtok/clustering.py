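"""Redundancy clustering and the leakage-free cluster-accumulation split.

Identity here is ungapped Hamming identity over equal-length windows ('N'
matches nothing), a deliberate simplification of the word-filtered banded
alignment used by external clustering tools; ``read_clstr`` imports the
external tool's output as the faithful alternative.

The split assigns *whole clusters*: sorted by size ascending, the smallest
clusters fill the test set first (targeting 20% of records), then the
validation set (15%), and everything remaining — the large families — goes
to training.  A cluster crossing a target boundary stays whole in the set
being filled, which is why achieved fractions deviate slightly from the
targets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .corpus import PromoterWindow

__all__ = [
    "Cluster",
    "SplitAssignment",
    "pairwise_identity",
    "greedy_cluster",
    "read_clstr",
    "write_clstr",
    "accumulate_split",
    "propagate_pairs",
    "filter_external",
]

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    id: int
    representative_id: str
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"cluster {self.id}: representative {self.representative_id!r} "
                "is not a member"
            )
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError(f"cluster {self.id}: duplicate members")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class SplitAssignment:
    partition: dict[str, str]  # record id -> {train, validation, test}
    achieved_fractions: dict[str, float]
    cluster_of: dict[str, int] = field(default_factory=dict)

    def ids(self, part: str) -> list[str]:
        return [i for i, p in self.partition.items() if p == part]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching positions; ungapped, case-insensitive, 'N' never
    matches."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    x = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    y = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    n = ord("N")
    matches = (x == y) & (x != n)
    return float(matches.sum()) / len(a)


def _kmer_fingerprint(seq: str, k: int = 6) -> set[int]:
    # all overlapping k-mers, hashed; pairs >= 80% identity share many
    return {hash(seq[i : i + k]) for i in range(len(seq) - k + 1)}


def greedy_cluster(
    sequences: dict[str, str], threshold: float = 0.80
) -> list[Cluster]:
    """Incremental greedy clustering at an identity threshold.

    Sequences are processed in deterministic order (length descending, id
    ascending); each joins the first existing representative with identity
    >= ``threshold``, otherwise founds a new cluster.  A k-mer fingerprint
    prefilter skips representative comparisons that share no non-overlapping
    6-mer (sequences above 80% identity necessarily share many).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    clusters: list[Cluster] = []
    reps: list[tuple[str, str, set[int]]] = []  # (id, seq, fingerprint)
    for sid in order:
        seq = sequences[sid]
        fp = _kmer_fingerprint(seq)
        placed = False
        for ci, (rid, rseq, rfp) in enumerate(reps):
            if len(rseq) == len(seq) and not (fp & rfp):
                continue
            if len(rseq) != len(seq):
                continue  # ungapped identity undefined across lengths
            if pairwise_identity(seq, rseq) >= threshold:
                clusters[ci].member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(len(clusters), sid, [sid]))
            reps.append((sid, seq, fp))
    return clusters


_CLSTR_HEADER = re.compile(r">Cluster\s+(\d+)")
_CLSTR_MEMBER = re.compile(r"^\d+\s+\d+(?:aa|nt),\s+>(.+?)\.\.\.\s+(.*)$")


def read_clstr(path: str) -> list[Cluster]:
    """Parse the standard ``.clstr`` dialect (">Cluster n" headers; members
    terminated by "*" for the representative or "at <pct>%")."""
    clusters: list[Cluster] = []
    current: list[tuple[str, bool]] | None = None

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        reps = [m for m, is_rep in current if is_rep]
        if len(reps) != 1:
            raise ValueError(
                f"{path}: cluster {len(clusters)} has {len(reps)} "
                "representatives (want exactly one '*')"
            )
        clusters.append(Cluster(len(clusters), reps[0], [m for m, _ in current]))
        current = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if _CLSTR_HEADER.match(line):
                flush()
                current = []
                continue
            m = _CLSTR_MEMBER.match(line)
            if m is None:
                raise ValueError(f"{path}:{lineno}: unparseable line {line!r}")
            if current is None:
                raise ValueError(
                    f"{path}:{lineno}: member line before any cluster header"
                )
            current.append((m.group(1), m.group(2).strip() == "*"))
    flush()
    return clusters


def write_clstr(clusters: list[Cluster], path: str, seq_len: int = 601) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f">Cluster {c.id}\n")
            for i, mid in enumerate(c.member_ids):
                tail = "*" if mid == c.representative_id else "at 90.00%"
                fh.write(f"{i}\t{seq_len}nt, >{mid}... {tail}\n")


def _tie_key(rep_id: str) -> str:
    import hashlib

    return hashlib.md5(rep_id.encode()).hexdigest()


def accumulate_split(
    clusters: list[Cluster],
    fractions: tuple[float, float, float] = (0.65, 0.15, 0.20),
) -> SplitAssignment:
    """Size-ascending whole-cluster accumulation into test, then validation,
    then train.

    ``fractions`` is (train, validation, test) and must sum to 1.  Filling
    proceeds smallest-cluster-first (ties by representative id ascending):
    clusters go to test while the cumulative record count is below the test
    target, then to validation likewise, and the remainder — including all
    large families — to train.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    total = sum(c.size for c in clusters)
    # ties in size break on a stable hash of the representative id: still
    # deterministic, but interleaves organisms instead of grouping ids that
    # share a lexicographic prefix into the same partition
    order = sorted(clusters, key=lambda c: (c.size, _tie_key(c.representative_id)))
    test_target = f_test * total
    val_target = f_val * total
    partition: dict[str, str] = {}
    cluster_of: dict[str, int] = {}
    counts = {"train": 0, "validation": 0, "test": 0}
    cum_test = cum_val = 0
    for c in order:
        if cum_test < test_target:
            part = "test"
            cum_test += c.size
        elif cum_val < val_target:
            part = "validation"
            cum_val += c.size
        else:
            part = "train"
        for mid in c.member_ids:
            partition[mid] = part
            cluster_of[mid] = c.id
        counts[part] += c.size
    if total and counts["train"] == 0:
        logger.warning(
            "degenerate split: no records left for training "
            "(a single cluster may exceed the test+validation targets)"
        )
    achieved = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return SplitAssignment(partition, achieved, cluster_of)


def propagate_pairs(
    assignment: SplitAssignment, windows: list[PromoterWindow]
) -> SplitAssignment:
    """Extend a positives-only split to negatives via their pair ids."""
    partition = dict(assignment.partition)
    for w in windows:
        if w.label != "negative":
            continue
        pid = w.paired_positive_id
        if pid not in assignment.partition:
            raise KeyError(
                f"negative {w.id} paired with unknown positive {pid!r}"
            )
        partition[w.id] = assignment.partition[pid]
    total = len(partition)
    achieved = {
        part: sum(1 for p in partition.values() if p == part) / total
        for part in ("train", "validation", "test")
    }
    return SplitAssignment(partition, achieved, dict(assignment.cluster_of))


def filter_external(
    external: list[PromoterWindow],
    training_pool: list[PromoterWindow],
    threshold: float = 0.80,
) -> list[PromoterWindow]:
    """External-species test-set filter.

    Drops external windows containing 'N', then clusters external and
    training sequences together at ``threshold`` and keeps only external
    windows whose cluster contains no training member (single-member with
    respect to the pool).
    """
    clean = [w for w in external if "N" not in w.sequence.upper()]
    ext_ids = {w.id for w in clean}
    pool = {w.id: w.sequence for w in training_pool}
    combined = dict(pool)
    combined.update({w.id: w.sequence for w in clean})
    clusters = greedy_cluster(combined, threshold)
    keep: set[str] = set()
    for c in clusters:
        members = set(c.member_ids)
        if members <= ext_ids:
            keep |= members
    return [w for w in clean if w.id in keep]
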