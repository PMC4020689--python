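"""Pairwise assemblage comparison and the Index of Rank-abundance Change.

The IRC measures how much the rank-abundance structure of an assemblage
changed between two samples A and B of the same site: species of the union
A u B are ranked by descending abundance within each sample, absent species
take rank S_present + 1, and

    IRC = sum_i |R_A(sp_i) - R_B(sp_i)| / |A u B|

i.e. the city-block distance between the two rank vectors, normalized by the
union richness so sites of different richness are comparable. IRC(A, A) = 0
and IRC rises as species reorder, appear, or disappear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from .community import CommunitySample

__all__ = [
    "RankedSample",
    "IRCResult",
    "TurnoverSummary",
    "Dendrogram",
    "renkonen",
    "chord_distance",
    "ward_cluster",
    "rank_species",
    "irc",
    "turnover",
    "pair_merges_first",
]


@dataclass(frozen=True)
class RankedSample:
    """Integer ranks for every species of a comparison universe.

    Present species hold ranks 1..S_present (descending abundance, species
    name breaking ties); absent universe species share the absent rank.
    """

    ranks: Mapping[str, int]
    s_present: int
    absent_rank: int


@dataclass(frozen=True)
class IRCResult:
    value: float
    n_union: int
    shifts: Mapping[str, int]


@dataclass(frozen=True)
class TurnoverSummary:
    """Set arithmetic on the species present before versus now."""

    s_before: int
    s_now: int
    shared: int
    only_before: int
    only_now: int
    union: int


@dataclass(frozen=True)
class Dendrogram:
    """Ward-linkage merge tree over community samples."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        root = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def _union_vectors(
    A: CommunitySample, B: CommunitySample
) -> tuple[list[str], np.ndarray, np.ndarray]:
    species = sorted(A.species | B.species)
    a = np.array([A.abundance.get(sp, 0.0) for sp in species])
    b = np.array([B.abundance.get(sp, 0.0) for sp in species])
    return species, a, b


def renkonen(A: CommunitySample, B: CommunitySample) -> float:
    """Renkonen minimum percentage similarity, in [0, 1].

    PS = sum_i min(p_Ai, p_Bi) over the species union, with p the relative
    aAD within each sample. 1 means identical relative-abundance profiles,
    0 means disjoint species sets.
    """
    _, a, b = _union_vectors(A, B)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both samples must contain individuals")
    return float(np.minimum(a / a.sum(), b / b.sum()).sum())


def chord_distance(A: CommunitySample, B: CommunitySample) -> float:
    """Chord distance: Euclidean distance between unit-normalized profiles.

    Ranges from 0 (proportional abundance vectors) to sqrt(2) (no shared
    species); invariant to rescaling either sample.
    """
    _, a, b = _union_vectors(A, B)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must contain individuals")
    return float(np.linalg.norm(a / na - b / nb))


def ward_cluster(samples: Sequence[CommunitySample]) -> Dendrogram:
    """Minimum-variance (Ward) clustering of samples on chord distances.

    Samples are embedded as unit-normalized abundance vectors over the full
    species union, where the chord distance is plain Euclidean distance, so
    Ward linkage is exact. Merge heights follow SciPy's Ward convention
    (square root of the variance increase times 2); for two samples the
    single merge height equals their chord distance.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {labels}")
    species = sorted(set().union(*(s.species for s in samples)))
    X = np.array(
        [[s.abundance.get(sp, 0.0) for sp in species] for s in samples]
    )
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("every sample must contain individuals")
    Z = linkage(X / norms, method="ward")
    return Dendrogram(labels=tuple(labels), linkage_matrix=Z)


def pair_merges_first(dendrogram: Dendrogram, label_a: str, label_b: str) -> bool:
    """True if the two leaves form a cluster of exactly themselves."""
    labels = dendrogram.labels
    ia, ib = labels.index(label_a), labels.index(label_b)
    Z = dendrogram.linkage_matrix
    for row in Z:
        if {int(row[0]), int(row[1])} == {ia, ib}:
            return True
    return False


def rank_species(
    sample: CommunitySample,
    universe: Iterable[str] | None = None,
    *,
    absent_policy: str = "s_plus_one",
) -> RankedSample:
    """Assign abundance ranks over a comparison universe.

    Present species get ranks 1..S_present by descending aAD (ties broken
    lexicographically by name). Universe species absent from the sample all
    take the absent rank: S_present + 1 by default ("just below the last
    present species"), or |universe| under ``absent_policy="union_size"``.
    """
    present = sorted(sample.abundance.items(), key=lambda kv: (-kv[1], kv[0]))
    universe_set = set(universe) if universe is not None else set(sample.abundance)
    missing = set(sample.abundance) - universe_set
    if missing:
        raise ValueError(f"universe must cover the sample; missing {sorted(missing)}")
    s_present = len(present)
    if absent_policy == "s_plus_one":
        absent_rank = s_present + 1
    elif absent_policy == "union_size":
        absent_rank = max(len(universe_set), s_present + 1)
    else:
        raise ValueError(f"unknown absent_policy {absent_policy!r}")
    ranks = {sp: r for r, (sp, _) in enumerate(present, start=1)}
    for sp in universe_set - set(ranks):
        ranks[sp] = absent_rank
    return RankedSample(ranks=ranks, s_present=s_present, absent_rank=absent_rank)


def irc(
    A: CommunitySample,
    B: CommunitySample,
    *,
    absent_policy: str = "s_plus_one",
) -> IRCResult:
    """Index of Rank-abundance Change between two samples of one site.

    Mean absolute rank shift over the species union: the city-block distance
    between the two rank vectors divided by |A u B|.
    """
    if not A.abundance or not B.abundance:
        raise ValueError("both samples must be non-empty")
    universe = A.species | B.species
    ra = rank_species(A, universe, absent_policy=absent_policy).ranks
    rb = rank_species(B, universe, absent_policy=absent_policy).ranks
    shifts = {sp: abs(ra[sp] - rb[sp]) for sp in sorted(universe)}
    n_union = len(universe)
    return IRCResult(
        value=sum(shifts.values()) / n_union, n_union=n_union, shifts=shifts
    )


def turnover(A: CommunitySample, B: CommunitySample) -> TurnoverSummary:
    """Species-set turnover between a before sample A and a now sample B."""
    sa, sb = A.species, B.species
    shared = len(sa & sb)
    return TurnoverSummary(
        s_before=len(sa),
        s_now=len(sb),
        shared=shared,
        only_before=len(sa) - shared,
        only_now=len(sb) - shared,
        union=len(sa | sb),
    )
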