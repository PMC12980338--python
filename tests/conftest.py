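"""Shared fixtures: small synthetic corpora generated at test time."""

import numpy as np
import pytest

import promtok as pt


@pytest.fixture(scope="session")
def epd8():
    return pt.generate_phylogeny(preset="epd8")


@pytest.fixture(scope="session")
def small_sim(epd8):
    """Three organisms, 40 promoters each, with planted families."""
    cfg = pt.SimConfig(
        n_organisms=3,
        promoters_per_organism=40,
        chromosome_length=80_000,
        family_count=3,
        family_size=3,
        family_identity=0.9,
        seed=11,
    )
    genomes = pt.synthesize_genome_set(cfg, epd8)
    return cfg, genomes


@pytest.fixture(scope="session")
def small_windows(small_sim):
    cfg, genomes = small_sim
    return pt.positive_windows(genomes, cfg.window_halfwidth)


@pytest.fixture(scope="session")
def tiny_vocab():
    """Non-overlapping 6-mer vocabulary over the plain alphabet."""
    return pt.build_kmer_vocab([], 6, overlapping=False)


def random_window(rng: np.random.Generator, length: int = 601) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
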