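"""Organism phylogenies used to drive composition drift and curricula.

Distances are divergence-time-like (MYA-scale arbitrary units).  Matrices are
ultrametric: the distance between two organisms is the height of their most
recent common ancestor, so ``max(d(a,c), d(b,c)) >= d(a,b)`` for all triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhylogenyTable", "generate_phylogeny", "nearest_species"]


@dataclass
class PhylogenyTable:
    """Ordered organism names with a symmetric divergence-time matrix."""

    organisms: list[str]
    distance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        n = len(self.organisms)
        if self.distance.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.distance.shape} does not match "
                f"{n} organisms"
            )
        if not np.allclose(self.distance, self.distance.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.distance) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")
        if len(set(self.organisms)) != n:
            raise ValueError("organism names must be unique")

    def index(self, organism: str) -> int:
        try:
            return self.organisms.index(organism)
        except ValueError:
            raise KeyError(f"unknown organism {organism!r}") from None

    def distance_between(self, a: str, b: str) -> float:
        return float(self.distance[self.index(a), self.index(b)])

    def distances_from(self, target: str) -> dict[str, float]:
        i = self.index(target)
        return {o: float(self.distance[i, j]) for j, o in enumerate(self.organisms)}


# Divergence heights for the eight-organism preset.  Magnitudes are
# MYA-like placeholders; only the ordinal structure matters: the four
# organisms closest to the reference are the reference itself, the
# macaque-like, the mouse-like and the rat-like organism.
_EPD8_MERGES: list[tuple[frozenset[str], float]] = [
    (frozenset({"reference", "mulatta_like"}), 29.0),
    (frozenset({"mouse_like", "rat_like"}), 13.0),
    (frozenset({"reference", "mulatta_like", "mouse_like", "rat_like"}), 87.0),
    (
        frozenset(
            {"reference", "mulatta_like", "mouse_like", "rat_like", "dog_like"}
        ),
        94.0,
    ),
]
_EPD9_ORDER = [
    "reference",
    "mulatta_like",
    "mouse_like",
    "rat_like",
    "dog_like",
    "chicken_like",
    "zebrafish_like",
    "fly_like",
    "worm_like",
]
_OUTGROUP_HEIGHTS = {
    "chicken_like": 319.0,
    "zebrafish_like": 429.0,
    "fly_like": 694.0,
    "worm_like": 736.0,
}


def _preset_table(organisms: list[str]) -> PhylogenyTable:
    n = len(organisms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = organisms[i], organisms[j]
            h = None
            for members, height in _EPD8_MERGES:
                if a in members and b in members:
                    h = height
                    break
            if h is None:
                # one of the pair is an outgroup: LCA height is the deeper
                # of the two outgroup join heights
                h = max(
                    _OUTGROUP_HEIGHTS.get(a, 0.0), _OUTGROUP_HEIGHTS.get(b, 0.0)
                )
            dist[i, j] = dist[j, i] = h
    return PhylogenyTable(organisms, dist)


_PRESETS = {
    "epd8": [o for o in _EPD9_ORDER if o != "dog_like"],
    "epd9": list(_EPD9_ORDER),
}


def generate_phylogeny(
    n: int | None = None, seed: int | None = None, preset: str | None = None
) -> PhylogenyTable:
    """Build a phylogeny, either from a named preset or at random.

    Random tables are ultrametric by construction: organisms coalesce
    pairwise at strictly increasing heights, and the distance between two
    organisms is the height at which their lineages merge.

    Parameters
    ----------
    n : int, optional
        Number of organisms (random mode). Must be >= 2.
    seed : int, optional
        Seed for the random topology and heights.
    preset : str, optional
        Name of a built-in table ("epd8": eight organisms whose nearest-4
        set for ``reference`` is {reference, mulatta_like, mouse_like,
        rat_like}; "epd9": the same plus an external dog-like organism).
    """
    if preset is not None:
        try:
            return _preset_table(_PRESETS[preset])
        except KeyError:
            raise KeyError(
                f"unknown phylogeny preset {preset!r}; "
                f"available: {sorted(_PRESETS)}"
            ) from None
    if n is None or n < 2:
        raise ValueError("need n >= 2 organisms (or a preset name)")
    rng = np.random.default_rng(seed)
    names = [f"org_{i:02d}" for i in range(n)]
    dist = np.zeros((n, n))
    # coalescent-style: each lineage starts as its own cluster; merge two
    # random clusters at an increasing height until one remains
    clusters: list[list[int]] = [[i] for i in range(n)]
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.exponential(50.0)) + 1.0
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                dist[a, b] = dist[b, a] = height
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return PhylogenyTable(names, dist)


def nearest_species(phylo: PhylogenyTable, target: str, m: int = 4) -> list[str]:
    """The ``m`` organisms closest to ``target``, target included (d=0).

    Ties at the cut are broken by organism name ascending.
    """
    if m > len(phylo.organisms):
        raise ValueError(
            f"m={m} exceeds the {len(phylo.organisms)} organisms in the table"
        )
    d = phylo.distances_from(target)  # raises KeyError for unknown target
    ranked = sorted(d.items(), key=lambda kv: (kv[1], kv[0]))
    return [name for name, _ in ranked[:m]]
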