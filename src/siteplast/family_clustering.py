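"""Clustering of superfamily members into sequence and structural subfamilies.

Two partitions are produced: s60 clusters (greedy, CD-HIT style, at 60%
pairwise sequence identity -- a proxy for functionally coherent subgroups)
and structural clusters (single-linkage components of the graph whose edges
connect domain pairs with normalised RMSD below a cutoff, 9.0 A by default).
A superfamily with at least two structural clusters is called structurally
diverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .pairwise_align import StructuralAlignment, alignment_nrmsd
from .structure_io import DomainStructure


@dataclass
class ClusterSet:
    """A partition of domain ids into clusters.

    ``kind`` is ``"s60"`` (sequence identity threshold in ``parameter``) or
    ``"structural"`` (normalised-RMSD cutoff in Angstroms in ``parameter``).
    """

    kind: str
    clusters: list[set[str]]
    parameter: float

    def __post_init__(self) -> None:
        if self.kind not in ("s60", "structural"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        if len(self.clusters) < 1:
            raise ValueError("a ClusterSet needs at least one cluster")
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def domain_ids(self) -> set[str]:
        return set().union(*self.clusters)

    def assignment(self) -> dict[str, int]:
        """domain id -> cluster index (in cluster order)."""
        return {d: i for i, c in enumerate(self.clusters) for d in c}

    def labels(self, prefix: str | None = None) -> dict[str, str]:
        prefix = prefix or self.kind
        return {d: f"{prefix}_{i:03d}" for i, c in enumerate(self.clusters) for d in c}


# ---------------------------------------------------------------------------
# Sequence identity and s60 clustering
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _global_aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned positions over the shorter sequence.

    Global Needleman-Wunsch under BLOSUM62 (gap open 10, extend 0.5); the
    shorter-sequence denominator follows the CD-HIT convention, so a perfect
    prefix counts as identity 1.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_a == seq_b:
        return 1.0
    aln = _global_aligner().align(seq_a, seq_b)[0]
    identities = aln.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def cluster_s60(domains: Iterable[DomainStructure],
                threshold: float = 0.60) -> ClusterSet:
    """Greedy longest-first clustering at a sequence-identity threshold.

    Domains are visited by (length descending, id ascending); each joins the
    first existing cluster whose seed it matches at >= threshold, otherwise
    it seeds a new cluster.  Duplicated input records are collapsed first,
    so the result is invariant to duplication.
    """
    unique: dict[str, DomainStructure] = {}
    for d in domains:
        unique.setdefault(d.domain_id, d)
    ordered = sorted(unique.values(), key=lambda d: (-d.length, d.domain_id))
    if not ordered:
        raise ValueError("no domains to cluster")
    seeds: list[DomainStructure] = []
    clusters: list[set[str]] = []
    for dom in ordered:
        for seed, members in zip(seeds, clusters):
            if sequence_identity(seed.sequence, dom.sequence) >= threshold:
                members.add(dom.domain_id)
                break
        else:
            seeds.append(dom)
            clusters.append({dom.domain_id})
    return ClusterSet(kind="s60", clusters=clusters, parameter=threshold)


# ---------------------------------------------------------------------------
# Structural clustering
# ---------------------------------------------------------------------------

PairKey = tuple[str, str]


def _lookup_pair(nrmsd: Mapping[PairKey, float], a: str, b: str) -> float:
    if (a, b) in nrmsd:
        return nrmsd[(a, b)]
    if (b, a) in nrmsd:
        return nrmsd[(b, a)]
    raise KeyError(f"missing normalised RMSD for pair ({a}, {b})")


def compute_nrmsd_pairs(domains: Sequence[DomainStructure],
                        aligner: Callable[[DomainStructure, DomainStructure],
                                          StructuralAlignment],
                        ) -> dict[PairKey, float]:
    """All-pairs normalised RMSD from pairwise alignments."""
    out: dict[PairKey, float] = {}
    for i, da in enumerate(domains):
        for db in domains[i + 1:]:
            aln = aligner(da, db)
            out[(da.domain_id, db.domain_id)] = alignment_nrmsd(aln, da.length, db.length)
    return out


def cluster_structures(domain_ids: Sequence[str],
                       nrmsd: Mapping[PairKey, float],
                       cutoff: float = 9.0) -> ClusterSet:
    """Single-linkage structural clusters at a normalised-RMSD cutoff.

    Two domains share a cluster iff they are connected by a chain of pairs
    with nRMSD < cutoff (connected components of the thresholded graph).
    Every pair must be present in ``nrmsd``; a missing pair is an error.
    """
    ids = sorted(set(domain_ids))
    if not ids:
        raise ValueError("no domains to cluster")
    n = len(ids)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if _lookup_pair(nrmsd, ids[i], ids[j]) < cutoff:
                rows.extend((i, j))
                cols.extend((j, i))
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for idx, lab in zip(ids, labels):
        clusters[lab].add(idx)
    clusters.sort(key=lambda c: min(c))
    return ClusterSet(kind="structural", clusters=clusters, parameter=cutoff)


def is_structurally_diverse(cluster_set: ClusterSet) -> bool:
    """True iff the superfamily has at least 2 structural clusters."""
    if cluster_set.kind != "structural":
        raise ValueError("diversity is defined on structural cluster sets")
    return cluster_set.n_clusters >= 2
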