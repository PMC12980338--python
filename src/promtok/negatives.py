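"""Negative-set construction: shuffled promoters and genomic fragments.

Two strategies, mirroring the field's two standard recipes:

* **positive-promoter-shuffled** — each positive window is cut into 25
  contiguous 24-nt segments (covering positions 0..599; the 601st base is
  never touched); 8 segments are drawn uniformly without replacement and
  independently permuted in place, the other 17 are left byte-identical.
  The whole-sequence nucleotide multiset is preserved by construction.
* **random-non-promoter-fragments** — a window centered on a random TSS
  drawn from the same chromosome as the paired positive, at least 600 nt
  from every positive TSS and every previously accepted negative TSS.

Every negative records the id of the positive it balances, so split
propagation can keep pairs together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import GenomeSet, PromoterWindow, TSSRecord, extract_window

__all__ = [
    "PerturbationMask",
    "make_shuffled_negative",
    "sample_fragment_tss",
    "build_negative_set",
    "expected_tata_frequency",
    "PlacementExhausted",
]

logger = logging.getLogger(__name__)


class PlacementExhausted(RuntimeError):
    """No fragment TSS satisfying the distance constraint was found."""


@dataclass
class PerturbationMask:
    """Which of the fixed segments of a shuffled negative were permuted."""

    flags: list[bool]
    segment_length: int = 24

    def __post_init__(self) -> None:
        self.flags = list(self.flags)

    @property
    def n_segments(self) -> int:
        return len(self.flags)

    @property
    def n_perturbed(self) -> int:
        return sum(self.flags)

    def segment_bounds(self, i: int) -> tuple[int, int]:
        return i * self.segment_length, (i + 1) * self.segment_length

    def perturbed_positions(self) -> list[int]:
        out = []
        for i, f in enumerate(self.flags):
            if f:
                a, b = self.segment_bounds(i)
                out.extend(range(a, b))
        return out


def make_shuffled_negative(
    positive: str,
    n_segments: int = 25,
    seg_len: int = 24,
    n_perturb: int = 8,
    rng: np.random.Generator | None = None,
    mode: str = "permute",
) -> tuple[str, PerturbationMask]:
    """Perturb ``n_perturb`` of ``n_segments`` fixed segments of a positive.

    ``mode="permute"`` (default) shuffles each chosen segment's bases in
    place, preserving the sequence's nucleotide multiset exactly.
    ``mode="substitute"`` replaces chosen segments with i.i.d. uniform
    A/C/G/T draws (sensitivity-analysis variant; composition not preserved).

    Positions outside chosen segments — including any tail not covered by
    the ``n_segments * seg_len`` tiling, e.g. the final base of a 601-nt
    window — are returned byte-identical to the input.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_segments * seg_len > len(positive):
        raise ValueError(
            f"{n_segments} segments of {seg_len} nt do not fit a "
            f"{len(positive)}-nt sequence"
        )
    if n_perturb > n_segments:
        raise ValueError("n_perturb exceeds n_segments")
    if mode not in ("permute", "substitute"):
        raise ValueError(f"unknown mode {mode!r}")
    chosen = rng.choice(n_segments, size=n_perturb, replace=False)
    flags = [False] * n_segments
    arr = np.frombuffer(positive.encode(), dtype=np.uint8).copy()
    for s in sorted(int(c) for c in chosen):
        flags[s] = True
        a, b = s * seg_len, (s + 1) * seg_len
        if mode == "permute":
            arr[a:b] = arr[a:b][rng.permutation(seg_len)]
        else:
            arr[a:b] = np.frombuffer(b"ACGT", dtype=np.uint8)[
                rng.integers(0, 4, seg_len)
            ]
    return arr.tobytes().decode("ascii"), PerturbationMask(flags, seg_len)


def sample_fragment_tss(
    chrom_seq: str,
    occupied_tss: list[int],
    min_dist: int = 600,
    halfwidth: int = 300,
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
) -> int:
    """Draw a TSS for a fragment negative on this chromosome.

    The returned position admits a full window (``halfwidth <= p <
    len - halfwidth``) and lies at least ``min_dist`` nt from every
    position in ``occupied_tss`` (positives plus previously accepted
    negatives).  The caller is responsible for appending the result to
    ``occupied_tss`` before the next draw.

    Raises :class:`PlacementExhausted` after ``max_tries`` rejected draws.
    """
    if rng is None:
        rng = np.random.default_rng()
    lo, hi = halfwidth, len(chrom_seq) - halfwidth
    if hi <= lo:
        raise ValueError("chromosome shorter than one window")
    occ = np.asarray(occupied_tss, dtype=int)
    for _ in range(max_tries):
        p = int(rng.integers(lo, hi))
        if occ.size == 0 or int(np.abs(occ - p).min()) >= min_dist:
            return p
    raise PlacementExhausted(
        f"no position >= {min_dist} nt from all {occ.size} occupied TSSs "
        f"after {max_tries} tries"
    )


def build_negative_set(
    positives: list[PromoterWindow],
    genomes: GenomeSet | None,
    strategy: str,
    seed: int,
    min_dist: int = 600,
    max_tries: int = 1000,
    mode: str = "permute",
    n_segments: int = 25,
    seg_len: int = 24,
    n_perturb: int = 8,
) -> list[PromoterWindow]:
    """One negative per positive, paired by id.

    ``strategy="shuffled"`` needs no genomes; ``strategy="fragment"``
    requires ``genomes`` to cover every positive's chromosome and draws
    each negative from the same chromosome as its paired positive.
    Fragment placements that exhaust ``max_tries`` are logged and skipped,
    leaving an explicit imbalance.
    """
    rng = np.random.default_rng(seed)
    negatives: list[PromoterWindow] = []
    if strategy == "shuffled":
        for pos in positives:
            seq, mask = make_shuffled_negative(
                pos.sequence, n_segments, seg_len, n_perturb, rng, mode
            )
            negatives.append(
                PromoterWindow(
                    id=f"{pos.id}_neg",
                    organism=pos.organism,
                    sequence=seq,
                    label="negative",
                    source="shuffled_negative",
                    paired_positive_id=pos.id,
                    mask=mask.flags,
                )
            )
        return negatives
    if strategy != "fragment":
        raise ValueError(f"unknown strategy {strategy!r}")
    if genomes is None:
        raise ValueError("fragment strategy requires genomes")
    halfwidth = positives[0].halfwidth if positives else 300
    # occupied set per (organism, chrom): all positive TSSs up front,
    # accepted negatives appended as they are placed
    occupied: dict[tuple[str, str], list[int]] = {}
    for rec in genomes.tss_table:
        occupied.setdefault((rec.organism, rec.chrom), []).append(rec.pos)
    skipped = 0
    for pos in positives:
        if pos.chrom is None:
            raise ValueError(f"positive {pos.id} lacks chromosome provenance")
        chrom_seq = genomes.chromosome(pos.organism, pos.chrom)  # KeyError if absent
        occ = occupied.setdefault((pos.organism, pos.chrom), [])
        try:
            p = sample_fragment_tss(
                chrom_seq, occ, min_dist, halfwidth, rng, max_tries
            )
        except PlacementExhausted:
            skipped += 1
            logger.warning(
                "fragment placement exhausted for %s on %s:%s; skipping",
                pos.id,
                pos.organism,
                pos.chrom,
            )
            continue
        occ.append(p)
        rec = TSSRecord(pos.organism, pos.chrom, p, "+", "unknown")
        negatives.append(
            PromoterWindow(
                id=f"{pos.id}_neg",
                organism=pos.organism,
                sequence=extract_window(chrom_seq, rec, halfwidth),
                label="negative",
                source="fragment_negative",
                paired_positive_id=pos.id,
                chrom=pos.chrom,
                tss_pos=p,
            )
        )
    if skipped:
        logger.warning(
            "negative set imbalanced: %d of %d placements failed",
            skipped,
            len(positives),
        )
    return negatives


def expected_tata_frequency(
    p_tata: float, n_perturb: int = 8, n_segments: int = 25
) -> float:
    """Expected TATA-box frequency (in %) surviving segment perturbation.

    A motif survives iff its segment is unperturbed, so a positive-class
    prevalence of ``p_tata`` percent retains
    ``p_tata * (n_segments - n_perturb) / n_segments`` percent in the
    shuffled negatives (12.9% -> 8.772, i.e. 8.8 to one decimal, at the
    default 8-of-25 scheme).
    """
    if not 0.0 <= p_tata <= 100.0:
        raise ValueError("p_tata is a percentage in [0, 100]")
    if n_perturb > n_segments:
        raise ValueError("n_perturb exceeds n_segments")
    return p_tata * (n_segments - n_perturb) / n_segments
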