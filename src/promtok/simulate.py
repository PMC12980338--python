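"""Synthetic multi-organism promoter corpora.

The generator emulates the statistical structure the downstream pipeline
assumes of curated promoter data:

* 601-nt TSS-centered windows with a TATA-box planted ~30 nt upstream in a
  configurable fraction of promoters (default 12.9%, the prevalence the
  positive class is modelled on);
* a fixed downstream motif planted near +90 so positional attribution has a
  recoverable signal;
* per-organism background "dialects": a first-order (dinucleotide) chain
  whose composition drifts away from the reference organism proportionally
  to phylogenetic distance;
* chromosome-scale background so fragment negatives can be sampled;
* near-duplicate promoter families that co-cluster at the 80% identity
  threshold, exercising the redundancy-aware split;
* rare ambiguous 'N' bases, never inside planted motifs.

All randomness flows through one seeded generator; fixed seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from .corpus import GenomeSet, PromoterWindow, TSSRecord, extract_window
from .phylogeny import PhylogenyTable

__all__ = [
    "SimConfig",
    "synthesize_genome_set",
    "positive_windows",
    "inject_redundancy",
    "save_config",
    "load_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")

#: TATA-box literal with one degenerate position (TATA[AT]A)
DEFAULT_TATA = "TATAAA"
#: fixed downstream element planted near +90
DEFAULT_DOWNSTREAM = "GGACGT"


@dataclass
class SimConfig:
    """Knobs of the synthetic corpus; defaults are the study conditions."""

    n_organisms: int = 8
    promoters_per_organism: int = 100
    chromosome_length: int = 250_000
    window_halfwidth: int = 300
    tata_fraction: float = 0.129
    tata_offset_range: tuple[int, int] = (-35, -25)
    tata_motif: str = DEFAULT_TATA
    downstream_motif: str = DEFAULT_DOWNSTREAM
    downstream_offset: int = 90
    downstream_strength: float = 0.9
    gc_drift_rate: float = 1.5e-4
    n_rate: float = 1e-4
    family_count: int = 5
    family_size: int = 3
    family_identity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tata_fraction", "downstream_strength", "n_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")
        if self.chromosome_length < 2 * self.window_halfwidth + 1:
            raise ValueError("chromosome shorter than one window")
        if not 0.8 < self.family_identity <= 1.0:
            raise ValueError(
                "family_identity must lie in (0.8, 1.0] so planted families "
                "co-cluster at the 80% identity threshold"
            )
        if self.family_count and self.family_size < 2:
            raise ValueError("family_size must be >= 2")
        self.tata_offset_range = tuple(self.tata_offset_range)  # type: ignore[assignment]

    @property
    def window_length(self) -> int:
        return 2 * self.window_halfwidth + 1


def save_config(config: SimConfig, path: str | Path) -> None:
    d = asdict(config)
    d["tata_offset_range"] = list(config.tata_offset_range)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["tata_offset_range"] = tuple(d["tata_offset_range"])
    return SimConfig(**d)


# ---------------------------------------------------------------------------
# background model


def _composition(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])  # A C G T


def _transition_matrix(gc: float, cpg_depletion: float = 0.2) -> np.ndarray:
    """First-order chain: stationary-ish composition with CpG suppression."""
    p = _composition(gc)
    T = np.tile(p, (4, 1))
    T[1, 2] *= cpg_depletion  # C -> G
    T /= T.sum(axis=1, keepdims=True)
    return T


def _markov_chromosome(length: int, T: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample a base-index array from a 4-state first-order chain."""
    cum = np.cumsum(T, axis=1)
    # tuples of plain floats: the tight loop below is ~3x faster than
    # per-step numpy indexing
    c = [tuple(row) for row in cum]
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    s = int(rng.integers(0, 4))
    for i in range(length):
        r = u[i]
        row = c[s]
        if r < row[0]:
            s = 0
        elif r < row[1]:
            s = 1
        elif r < row[2]:
            s = 2
        else:
            s = 3
        out[i] = s
    return out


def _indices_to_str(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# planting helpers (window frame <-> chromosome frame)


def _window_positions(tss: int, strand: str, halfwidth: int, idx: np.ndarray) -> np.ndarray:
    """Chromosome positions of window indices ``idx`` for a stranded TSS."""
    if strand == "+":
        return tss - halfwidth + idx
    return tss + halfwidth - idx


_COMP_IDX = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def _write_window_base(
    chrom: np.ndarray, pos: np.ndarray, strand: str, base_idx: np.ndarray
) -> None:
    chrom[pos] = base_idx if strand == "+" else _COMP_IDX[base_idx]


def _read_window_base(chrom: np.ndarray, pos: np.ndarray, strand: str) -> np.ndarray:
    raw = chrom[pos]
    return raw if strand == "+" else _COMP_IDX[raw]


_BASE_TO_IDX = {b: i for i, b in enumerate("ACGT")}


def _motif_indices(motif: str) -> np.ndarray:
    return np.array([_BASE_TO_IDX[b] for b in motif], dtype=np.int8)


# ---------------------------------------------------------------------------


def synthesize_genome_set(config: SimConfig, phylo: PhylogenyTable) -> GenomeSet:
    """Generate one chromosome per organism plus a planted TSS table.

    The returned :class:`GenomeSet` additionally carries

    * ``families``: organism -> list of families, each a list of TSS-table
      row indices, recording planted near-duplicate groups (oracle for
      clustering tests);
    * ``protected``: organism -> set of chromosome positions inside planted
      motifs (never mutated, never 'N').

    Raises a capacity ``ValueError`` when ``promoters_per_organism`` windows
    cannot be placed without overlap.
    """
    if config.n_organisms > len(phylo.organisms):
        raise ValueError(
            f"config asks for {config.n_organisms} organisms but the "
            f"phylogeny has {len(phylo.organisms)}"
        )
    organisms = phylo.organisms[: config.n_organisms]
    reference = organisms[0]
    rng = np.random.default_rng(config.seed)
    h = config.window_halfwidth
    L = config.chromosome_length
    n_prom = config.promoters_per_organism

    # non-overlapping placement slots
    usable = L - 2 * (h + 1)
    win = 2 * h + 2
    if n_prom * win > usable:
        raise ValueError(
            f"cannot place {n_prom} non-overlapping {2 * h + 1}-nt windows on a "
            f"{L}-nt chromosome"
        )
    slot = usable / n_prom

    base_gc = 0.41
    tata_idx = _motif_indices(config.tata_motif)
    down_idx = _motif_indices(config.downstream_motif)

    chromosomes: dict[str, dict[str, str]] = {}
    tss_table: list[TSSRecord] = []
    families: dict[str, list[list[int]]] = {}
    protected: dict[str, set[int]] = {}

    n_family_loci = config.family_count * config.family_size
    if n_family_loci > n_prom:
        raise ValueError("family_count * family_size exceeds promoters_per_organism")

    for org in organisms:
        d = phylo.distance_between(org, reference)
        gc = float(np.clip(base_gc - config.gc_drift_rate * d, 0.25, 0.65))
        chrom = _markov_chromosome(L, _transition_matrix(gc), rng)
        core_comp = _composition(min(gc + 0.06, 0.9))

        # jittered grid keeps consecutive TSSs >= one window apart
        jitter = rng.random(n_prom) * (slot - win)
        tss_pos = (h + 1 + np.arange(n_prom) * slot + jitter).astype(int)
        strands = np.where(rng.random(n_prom) < 0.5, "+", "-")
        has_tata = rng.random(n_prom) < config.tata_fraction
        has_down = rng.random(n_prom) < config.downstream_strength
        tata_off = rng.integers(
            config.tata_offset_range[0], config.tata_offset_range[1] + 1, n_prom
        )
        # degenerate TATA position 4: A or T
        tata_deg = rng.integers(0, 2, n_prom)

        prot: set[int] = set()
        org_rows: list[int] = []
        plant_plan: list[dict] = []
        for i in range(n_prom):
            plant_plan.append(
                {
                    "tss": int(tss_pos[i]),
                    "strand": str(strands[i]),
                    "tata": bool(has_tata[i]),
                    "down": bool(has_down[i]),
                    "tata_off": int(tata_off[i]),
                    "tata_deg": int(tata_deg[i]),
                }
            )

        # family members replicate their seed locus' plan (so the copied
        # window content stays aligned with the planted elements)
        fam_groups: list[list[int]] = []
        for f in range(config.family_count):
            seed_i = f * config.family_size
            members = list(range(seed_i, seed_i + config.family_size))
            for m in members[1:]:
                plan = dict(plant_plan[seed_i])
                plan["tss"] = plant_plan[m]["tss"]
                plan["strand"] = plant_plan[m]["strand"]
                plant_plan[m] = plan
            fam_groups.append(members)

        def plant(plan: dict) -> np.ndarray:
            """Plant core + motifs at a locus; return protected chrom positions."""
            tss, strand = plan["tss"], plan["strand"]
            prot_pos = []
            # GC-enriched core: resample -50..+50 i.i.d. from boosted comp
            core = np.arange(max(-50, -h), min(50, h) + 1)
            core_pos = _window_positions(tss, strand, h, core + h)
            core_draw = rng.choice(4, size=core.size, p=core_comp).astype(np.int8)
            _write_window_base(chrom, core_pos, strand, core_draw)
            if plan["tata"]:
                motif = tata_idx.copy()
                motif[4] = 0 if plan["tata_deg"] == 0 else 3  # A or T
                widx = np.arange(len(motif)) + plan["tata_off"] + h
                pos = _window_positions(tss, strand, h, widx)
                _write_window_base(chrom, pos, strand, motif)
                prot_pos.append(pos)
            if plan["down"]:
                widx = np.arange(len(down_idx)) + config.downstream_offset + h
                pos = _window_positions(tss, strand, h, widx)
                _write_window_base(chrom, pos, strand, down_idx)
                prot_pos.append(pos)
            return np.concatenate(prot_pos) if prot_pos else np.empty(0, dtype=int)

        fam_member_of = {}
        for grp in fam_groups:
            for m in grp[1:]:
                fam_member_of[m] = grp[0]

        win_len = 2 * h + 1
        seed_content: dict[int, np.ndarray] = {}
        for i, plan in enumerate(plant_plan):
            p = plant(plan)
            prot.update(int(x) for x in p)
            widx_all = np.arange(win_len)
            pos_all = _window_positions(plan["tss"], plan["strand"], h, widx_all)
            if i in fam_member_of:
                seed_i = fam_member_of[i]
                content = seed_content[seed_i].copy()
                # mutate exactly floor((1-identity)*L) unprotected positions
                n_mut = int((1.0 - config.family_identity) * win_len)
                prot_w = np.isin(_window_positions(plan["tss"], plan["strand"], h, widx_all), p) if p.size else np.zeros(win_len, bool)
                # protect the motif window indices of this locus
                free = np.flatnonzero(~prot_w)
                mut = rng.choice(free, size=min(n_mut, free.size), replace=False)
                shift = rng.integers(1, 4, size=mut.size).astype(np.int8)
                content[mut] = (content[mut] + shift) % 4
                _write_window_base(chrom, pos_all, plan["strand"], content)
            else:
                content = _read_window_base(chrom, pos_all, plan["strand"])
            seed_content[i] = content

        # sparse ambiguous bases, never inside planted motifs
        if config.n_rate > 0:
            n_sites = rng.random(L) < config.n_rate
            if prot:
                n_sites[np.fromiter(prot, int, len(prot))] = False
            chrom = chrom.astype(np.int16)
            chrom[n_sites] = 4
        seq = (
            np.frombuffer(b"ACGTN", dtype=np.uint8)[chrom].tobytes().decode("ascii")
        )

        chromosomes[org] = {"chr1": seq}
        row0 = len(tss_table)
        for i, plan in enumerate(plant_plan):
            tss_table.append(
                TSSRecord(
                    organism=org,
                    chrom="chr1",
                    pos=plan["tss"],
                    strand=plan["strand"],
                    promoter_class="TATA" if plan["tata"] else "nonTATA",
                )
            )
            org_rows.append(row0 + i)
        families[org] = [[row0 + m for m in grp] for grp in fam_groups]
        protected[org] = prot

    genomes = GenomeSet(chromosomes, tss_table)
    genomes.families = families  # type: ignore[attr-defined]
    genomes.protected = protected  # type: ignore[attr-defined]
    return genomes


def positive_windows(
    genomes: GenomeSet, halfwidth: int = 300
) -> list[PromoterWindow]:
    """Extract one positive window per TSS record (ids ``{org}_p{row:05d}``)."""
    out = []
    counters: dict[str, int] = {}
    for rec in genomes.tss_table:
        i = counters.get(rec.organism, 0)
        counters[rec.organism] = i + 1
        seq = extract_window(
            genomes.chromosome(rec.organism, rec.chrom), rec, halfwidth
        )
        out.append(
            PromoterWindow(
                id=f"{rec.organism}_p{i:05d}",
                organism=rec.organism,
                sequence=seq,
                label="positive",
                source="epd_like",
                chrom=rec.chrom,
                tss_pos=rec.pos,
                strand=rec.strand,
            )
        )
    return out


def inject_redundancy(
    windows: list[PromoterWindow],
    family_count: int,
    family_size: int,
    identity: float,
    seed: int,
) -> tuple[list[PromoterWindow], dict[str, list[str]]]:
    """Append near-duplicate families to a window list.

    The first ``family_count`` windows act as family seeds; each gains
    ``family_size - 1`` copies mutated at exactly ``floor((1-identity)*L)``
    positions, so every member's Hamming identity to its seed is >=
    ``identity``.  Returns the extended list plus ``family id -> member ids``
    (seed included) for oracle tests.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must lie in (0, 1]")
    if family_size < 2:
        raise ValueError("family_size must be >= 2")
    if not windows:
        return [], {}
    if family_count > len(windows):
        raise ValueError("more families requested than input windows")
    rng = np.random.default_rng(seed)
    out = list(windows)
    members: dict[str, list[str]] = {}
    for f in range(family_count):
        seed_w = windows[f]
        fam_id = f"fam{f:03d}"
        members[fam_id] = [seed_w.id]
        arr = np.frombuffer(seed_w.sequence.encode(), dtype=np.uint8)
        n_mut = int((1.0 - identity) * arr.size)
        for j in range(1, family_size):
            copy = arr.copy()
            if n_mut:
                pos = rng.choice(arr.size, size=n_mut, replace=False)
                for p in pos:
                    choices = [b for b in b"ACGT" if b != copy[p]]
                    copy[p] = choices[int(rng.integers(0, len(choices)))]
            new_id = f"{seed_w.id}_f{j}"
            out.append(
                PromoterWindow(
                    id=new_id,
                    organism=seed_w.organism,
                    sequence=copy.tobytes().decode("ascii"),
                    label=seed_w.label,
                    source=seed_w.source,
                    paired_positive_id=seed_w.paired_positive_id,
                    mask=list(seed_w.mask) if seed_w.mask is not None else None,
                )
            )
            members[fam_id].append(new_id)
    return out, members
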