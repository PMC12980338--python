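"""Sequence containers and I/O: TSS tables, promoter windows, genomes.

Internal coordinates are 0-based (half-open for spans); the on-disk TSV
convention is 1-based, strand-aware, matching how curated promoter databases
publish TSS positions.  Conversion happens only at the I/O boundary.

Promoter windows span ``-halfwidth .. +halfwidth`` around the TSS (601 nt at
the default halfwidth of 300), read 5'->3' on the promoter's own strand, so
TSS-relative offset ``o`` always maps to window index ``o + halfwidth``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TSSRecord",
    "PromoterWindow",
    "GenomeSet",
    "extract_window",
    "classify_tata",
    "reverse_complement",
    "load_tss_table",
    "write_tss_table",
    "write_dataset",
    "load_dataset",
    "write_genome_fasta",
    "load_genome_fasta",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default window halfwidth: windows run from -300 to +300 around the TSS
DEFAULT_HALFWIDTH = 300

#: TATA-box detection pattern and default scan interval (TSS-relative start
#: offsets); the motif sits ~25-35 nt upstream of the TSS
TATA_PATTERN = re.compile(r"TATA[AT]A")
DEFAULT_TATA_SCAN = (-40, -20)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TSSRecord:
    """One experimentally-anchored transcription start site."""

    organism: str
    chrom: str
    pos: int  # 0-based chromosome coordinate of the TSS base
    strand: str
    promoter_class: str = "unknown"  # {TATA, nonTATA, unknown}

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class PromoterWindow:
    """A TSS-centered window with its label and provenance.

    ``mask`` is the 25-flag segment-perturbation mask and is present iff the
    window is a shuffled negative; ``paired_positive_id`` is present iff the
    window is a negative.
    """

    id: str
    organism: str
    sequence: str
    label: str  # {positive, negative}
    source: str  # {epd_like, shuffled_negative, fragment_negative}
    paired_positive_id: str | None = None
    mask: list[bool] | None = None
    chrom: str | None = None
    tss_pos: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")
        if self.label == "negative" and self.paired_positive_id is None:
            raise ValueError(f"negative window {self.id} lacks paired_positive_id")
        if self.label == "positive" and self.paired_positive_id is not None:
            raise ValueError(f"positive window {self.id} carries a pair id")
        if (self.mask is not None) != (self.source == "shuffled_negative"):
            raise ValueError(
                f"window {self.id}: mask present iff source is shuffled_negative"
            )

    @property
    def halfwidth(self) -> int:
        return (len(self.sequence) - 1) // 2

    @property
    def tss_index(self) -> int:
        return self.halfwidth


class GenomeSet:
    """Per-organism chromosomes plus the attached TSS table."""

    def __init__(
        self,
        chromosomes: dict[str, dict[str, str]],
        tss_table: list[TSSRecord],
    ):
        self.chromosomes = chromosomes
        self.tss_table = tss_table
        for rec in tss_table:
            seq = self.chromosome(rec.organism, rec.chrom)
            if rec.pos >= len(seq):
                raise ValueError(
                    f"TSS {rec.organism}:{rec.chrom}:{rec.pos} beyond "
                    f"chromosome length {len(seq)}"
                )

    def chromosome(self, organism: str, chrom: str) -> str:
        try:
            return self.chromosomes[organism][chrom]
        except KeyError:
            raise KeyError(f"no chromosome {chrom!r} for organism {organism!r}") from None

    @property
    def organisms(self) -> list[str]:
        return list(self.chromosomes)


def extract_window(
    chrom_seq: str, tss: TSSRecord, halfwidth: int = DEFAULT_HALFWIDTH
) -> str:
    """Cut the ``2*halfwidth + 1`` nt window centered on a TSS.

    Minus-strand windows are reverse-complemented so the returned string
    reads 5'->3' on the promoter strand with the TSS base at index
    ``halfwidth``.
    """
    if tss.pos < halfwidth or tss.pos + halfwidth >= len(chrom_seq):
        raise IndexError(
            f"TSS at {tss.pos} too close to the chromosome edge for "
            f"halfwidth {halfwidth} (length {len(chrom_seq)})"
        )
    window = chrom_seq[tss.pos - halfwidth : tss.pos + halfwidth + 1]
    if tss.strand == "-":
        window = reverse_complement(window)
    return window


def classify_tata(
    window: str, scan_range: tuple[int, int] = DEFAULT_TATA_SCAN
) -> bool:
    """True iff a TATA-box (TATA[AT]A) starts inside ``scan_range``.

    ``scan_range`` is a closed TSS-relative interval of allowed motif start
    offsets.  'N' never matches.
    """
    halfwidth = (len(window) - 1) // 2
    lo, hi = scan_range
    if lo < -halfwidth or hi > halfwidth:
        raise ValueError(f"scan_range {scan_range} outside the window")
    for m in TATA_PATTERN.finditer(window):
        if lo <= m.start() - halfwidth <= hi:
            return True
    return False


# ---------------------------------------------------------------------------
# TSV / FASTA I/O


def load_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a 1-based strand-aware TSS TSV into 0-based records.

    Columns: organism, chrom, pos (1-based), strand, class.
    Lines starting with '#' are provenance/comments.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, "
                    f"got {len(parts)}"
                )
            organism, chrom, pos_s, strand, cls = parts
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: position column {pos_s!r} is not an integer"
                ) from None
            if pos1 < 1:
                raise ValueError(f"{path}:{lineno}: 1-based position must be >= 1")
            if cls not in ("TATA", "nonTATA", "unknown"):
                raise ValueError(f"{path}:{lineno}: bad promoter class {cls!r}")
            records.append(TSSRecord(organism, chrom, pos1 - 1, strand, cls))
    return records


def write_tss_table(
    records: Iterable[TSSRecord], path: str | Path, provenance: str | None = None
) -> None:
    """Write TSS records as a 1-based TSV (inverse of :func:`load_tss_table`)."""
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("# organism\tchrom\tpos\tstrand\tclass\n")
        for r in records:
            fh.write(
                f"{r.organism}\t{r.chrom}\t{r.pos + 1}\t{r.strand}\t"
                f"{r.promoter_class}\n"
            )


def _window_header(w: PromoterWindow) -> str:
    fields = [w.id, w.organism, w.label, w.source, w.paired_positive_id or "."]
    if w.mask is not None:
        fields.append("".join("1" if f else "0" for f in w.mask))
    return "|".join(fields)


def write_dataset(
    windows: Iterable[PromoterWindow], path: str | Path, provenance: str | None = None
) -> None:
    """Write windows as FASTA with ``id|organism|label|source|paired_id``
    headers (plus a 0/1 mask field for shuffled negatives), 80-column wrapped.

    A sidecar ``<path>.provenance.txt`` records tool version and context.
    """
    path = Path(path)
    recs = [
        SeqRecord(Seq(w.sequence), id=_window_header(w), description="")
        for w in windows
    ]
    seen: set[str] = set()
    for w_id in (r.id.split("|")[0] for r in recs):
        if w_id in seen:
            raise ValueError(f"duplicate window id {w_id!r}")
        seen.add(w_id)
    SeqIO.write(recs, path, "fasta")
    from . import __version__

    side = path.with_suffix(path.suffix + ".provenance.txt")
    side.write_text(
        f"tool=promtok {__version__}\n" + (f"{provenance}\n" if provenance else "")
    )


def load_dataset(path: str | Path) -> list[PromoterWindow]:
    """Inverse of :func:`write_dataset`; round-trips all record fields."""
    windows = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) not in (5, 6):
            raise ValueError(
                f"{path}: malformed header {rec.id!r} "
                "(want id|organism|label|source|paired_id[|mask])"
            )
        w_id, organism, label, source, paired = parts[:5]
        if w_id in seen:
            raise ValueError(f"{path}: duplicate window id {w_id!r}")
        seen.add(w_id)
        mask = None
        if len(parts) == 6:
            if not re.fullmatch(r"[01]+", parts[5]):
                raise ValueError(f"{path}: malformed mask field in {rec.id!r}")
            mask = [c == "1" for c in parts[5]]
        windows.append(
            PromoterWindow(
                id=w_id,
                organism=organism,
                sequence=str(rec.seq),
                label=label,
                source=source,
                paired_positive_id=None if paired == "." else paired,
                mask=mask,
            )
        )
    return windows


def write_genome_fasta(genomes: GenomeSet, path: str | Path) -> None:
    """One FASTA for the whole genome set; headers ``organism|chrom``."""
    recs = [
        SeqRecord(Seq(seq), id=f"{org}|{chrom}", description="")
        for org, chroms in genomes.chromosomes.items()
        for chrom, seq in chroms.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_genome_fasta(path: str | Path, tss_table: list[TSSRecord]) -> GenomeSet:
    chromosomes: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        org, _, chrom = rec.id.partition("|")
        if not chrom:
            raise ValueError(f"{path}: malformed genome header {rec.id!r}")
        chromosomes.setdefault(org, {})[chrom] = str(rec.seq)
    return GenomeSet(chromosomes, tss_table)
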