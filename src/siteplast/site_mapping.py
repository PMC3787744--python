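"""Mapping functional sites from every superfamily member onto a common
representative, and the coverage statistic built on that mapping.

The protocol: (1) pick the representative as the s60-cluster representative
with the highest cumulative structural-similarity score to all other
cluster representatives; (2) structurally align every member against it;
(3) project each member's annotated residues through the alignment onto
representative positions (residues aligned to gaps are ignored); (4) record,
per representative position and site type, which domains and which s60
clusters contributed.

Coverage of a site type is the fraction of representative positions touched
by at least one member.  Two confounders are filtered: representatives
shorter than 100 residues (small domains trivially reach high coverage) and
superfamilies where a single domain alone covers more than 50% of the
representative (high coverage then reflects one promiscuous member, not
site-location diversity across the superfamily).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

from .family_clustering import ClusterSet
from .pairwise_align import StructuralAlignment, similarity_score
from .structure_io import DomainStructure, SiteAnnotation

Aligner = Callable[[DomainStructure, DomainStructure], StructuralAlignment]

EXCLUSION_REASONS = ("none", "rep_too_short", "single_domain_dominance",
                     "no_site_data", "single_s60_cluster")


class SingleClusterError(ValueError):
    """Raised for superfamilies made of a single s60 cluster (excluded)."""


@dataclass
class RepresentativeProfile:
    """Per-position contributor bookkeeping on a superfamily representative.

    ``by_domain[site_type][domain_id]`` is the set of representative
    positions that domain's annotated residues map to;
    ``annotated_domains[site_type]`` records every domain holding at least
    one annotation of the type, whether or not any of its residues survived
    the gap filter (needed for the colocation denominator).
    """

    superfamily_id: str
    representative_id: str
    rep_length: int
    n_domains: int
    by_domain: dict[str, dict[str, set[int]]] = field(default_factory=dict)
    annotated_domains: dict[str, set[str]] = field(default_factory=dict)
    s60_assignment: dict[str, int] | None = None

    def contributors(self, site_type: str) -> list[set[str]]:
        """Per representative position, the set of contributing domain ids."""
        out: list[set[str]] = [set() for _ in range(self.rep_length)]
        for domain_id, positions in self.by_domain.get(site_type, {}).items():
            for p in positions:
                out[p].add(domain_id)
        return out

    def cluster_contributors(self, site_type: str) -> list[set[int]]:
        """Per representative position, the set of contributing s60 clusters."""
        if self.s60_assignment is None:
            raise ValueError("profile has no s60 assignment")
        out: list[set[int]] = [set() for _ in range(self.rep_length)]
        for domain_id, positions in self.by_domain.get(site_type, {}).items():
            cl = self.s60_assignment[domain_id]
            for p in positions:
                out[p].add(cl)
        return out

    def footprint(self, site_type: str) -> set[int]:
        """Union of all mapped positions of a site type."""
        out: set[int] = set()
        for positions in self.by_domain.get(site_type, {}).values():
            out |= positions
        return out

    @property
    def n_s60_clusters(self) -> int:
        if self.s60_assignment is None:
            raise ValueError("profile has no s60 assignment")
        return len(set(self.s60_assignment.values()))


@dataclass
class CoverageResult:
    superfamily_id: str
    site_type: str
    coverage: float
    n_contributing_domains: int
    excluded: bool = False
    exclusion_reason: str = "none"
    representative_id: str = ""
    rep_length: int = 0
    single_member: bool = False

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.excluded and self.exclusion_reason == "none":
            raise ValueError("excluded results must name a reason")


# ---------------------------------------------------------------------------
# Representative selection
# ---------------------------------------------------------------------------

def cluster_representatives(s60_clusters: ClusterSet) -> list[str]:
    """One designated representative per s60 cluster (first member by id)."""
    return sorted(min(c) for c in s60_clusters.clusters)


def select_representative(domains: Mapping[str, DomainStructure],
                          s60_clusters: ClusterSet,
                          aligner: Aligner) -> str:
    """The cluster representative with maximal cumulative similarity score.

    Scores are summed over pairwise structural alignments against all other
    cluster representatives; ties break to the lexicographically smallest
    domain id.  Single-cluster superfamilies are excluded from the analysis
    and raise :class:`SingleClusterError`.
    """
    reps = cluster_representatives(s60_clusters)
    if len(reps) < 2:
        raise SingleClusterError("excluded: single s60 cluster")
    totals = {r: 0.0 for r in reps}
    for i, ra in enumerate(reps):
        for rb in reps[i + 1:]:
            da, db = domains[ra], domains[rb]
            aln = aligner(da, db)
            sc = similarity_score(aln, da.length, db.length)
            totals[ra] += sc
            totals[rb] += sc
    best = max(reps, key=lambda r: (totals[r], ))  # noqa: C417 - explicit key
    # lexicographic tie-break: reps is sorted and max() keeps the first maximum
    return best


# ---------------------------------------------------------------------------
# Site projection
# ---------------------------------------------------------------------------

def map_domain_sites(rep: DomainStructure, member: DomainStructure,
                     alignment: StructuralAlignment,
                     site_annotation: SiteAnnotation) -> set[int]:
    """Project one member's annotated residues onto representative positions.

    The alignment may be stored in either orientation.  Annotated residues
    aligned to a gap contribute nothing.
    """
    if site_annotation.domain_id != member.domain_id:
        raise ValueError(
            f"annotation is for {site_annotation.domain_id}, not {member.domain_id}"
        )
    if (alignment.domain_a, alignment.domain_b) == (member.domain_id, rep.domain_id):
        member_to_rep = dict(alignment.pairs)
    elif (alignment.domain_a, alignment.domain_b) == (rep.domain_id, member.domain_id):
        member_to_rep = {j: i for i, j in alignment.pairs}
    else:
        raise ValueError(
            f"alignment ({alignment.domain_a}, {alignment.domain_b}) does not "
            f"involve {member.domain_id} and {rep.domain_id}"
        )
    out: set[int] = set()
    for ref in site_annotation.residues:
        pos = member.index_of(ref)
        rep_pos = member_to_rep.get(pos)
        if rep_pos is not None:
            out.add(rep_pos)
    return out


def identity_alignment(domain: DomainStructure) -> StructuralAlignment:
    return StructuralAlignment(domain.domain_id, domain.domain_id,
                               [(i, i) for i in range(domain.length)],
                               rmsd=0.0, score=100.0)


def build_profile(superfamily_id: str,
                  domains: Mapping[str, DomainStructure],
                  representative_id: str,
                  alignments: Mapping[str, StructuralAlignment],
                  annotations: Iterable[SiteAnnotation],
                  s60_clusters: ClusterSet | None = None) -> RepresentativeProfile:
    """Union the mapped positions of every member, per site type.

    ``alignments`` maps member id -> alignment with the representative (any
    orientation); the representative itself may be omitted (identity is
    implied).  A member carrying annotations but lacking an alignment is an
    error.
    """
    rep = domains[representative_id]
    profile = RepresentativeProfile(
        superfamily_id=superfamily_id,
        representative_id=representative_id,
        rep_length=rep.length,
        n_domains=len(domains),
        s60_assignment=s60_clusters.assignment() if s60_clusters else None,
    )
    for ann in annotations:
        member = domains.get(ann.domain_id)
        if member is None:
            raise KeyError(f"annotation for unknown domain {ann.domain_id}")
        if ann.domain_id == representative_id:
            aln = identity_alignment(rep)
        else:
            aln = alignments.get(ann.domain_id)
            if aln is None:
                raise KeyError(
                    f"member {ann.domain_id} has annotations but no alignment "
                    f"with representative {representative_id}"
                )
        positions = map_domain_sites(rep, member, aln, ann)
        profile.annotated_domains.setdefault(ann.site_type, set()).add(ann.domain_id)
        per_dom = profile.by_domain.setdefault(ann.site_type, {})
        per_dom.setdefault(ann.domain_id, set()).update(positions)
    return profile


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def coverage(profile: RepresentativeProfile, site_type: str,
             min_rep_length: int = 100, dominance: float = 0.5,
             apply_length_filter: bool = True,
             apply_dominance_filter: bool = True) -> CoverageResult:
    """Coverage of the representative by one site type, with the two filters.

    coverage = |positions with >= 1 contributor| / rep_length.  The
    denominator is always the full representative length, including
    positions unaligned in some members.  Exclusions: representative shorter
    than ``min_rep_length``; any single domain whose own mapped positions
    exceed ``dominance`` of the representative (strict inequality).  A
    superfamily with no annotation of the type scores coverage 0 and is
    reported, not excluded.
    """
    by_domain = profile.by_domain.get(site_type, {})
    cov = len(profile.footprint(site_type)) / profile.rep_length
    result = CoverageResult(
        superfamily_id=profile.superfamily_id, site_type=site_type,
        coverage=cov, n_contributing_domains=sum(1 for p in by_domain.values() if p),
        representative_id=profile.representative_id, rep_length=profile.rep_length,
    )
    if apply_length_filter and profile.rep_length < min_rep_length:
        result.excluded = True
        result.exclusion_reason = "rep_too_short"
        return result
    if apply_dominance_filter:
        for positions in by_domain.values():
            if len(positions) / profile.rep_length > dominance:
                result.excluded = True
                result.exclusion_reason = "single_domain_dominance"
                return result
    return result


# ---------------------------------------------------------------------------
# Heat-map fractions
# ---------------------------------------------------------------------------

#: colour scale: exactly 0 grey, then half-open 20% bands, 100% in red.
HEATMAP_COLOURS = ("grey", "blue", "green", "yellow", "orange", "red")


def colour_bin(fraction: float) -> str:
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return "grey"
    if fraction < 0.2:
        return "blue"
    if fraction < 0.4:
        return "green"
    if fraction < 0.6:
        return "yellow"
    if fraction < 0.8:
        return "orange"
    return "red"


@dataclass
class HeatmapFractions:
    site_type: str
    denominator: str
    denominator_count: int
    fractions: np.ndarray
    bins: list[str]


def heatmap_fractions(profile: RepresentativeProfile, site_type: str,
                      denominator: str = "domains") -> HeatmapFractions:
    """Per-position contributor fractions plus their colour bins.

    ``denominator`` counts either all member domains or all s60 clusters of
    the superfamily (both conventions are supported; the choice only rescales
    the fractions).
    """
    if denominator == "domains":
        count = profile.n_domains
        per_pos = profile.contributors(site_type)
    elif denominator == "s60_clusters":
        count = profile.n_s60_clusters
        per_pos = profile.cluster_contributors(site_type)
    else:
        raise ValueError("denominator must be 'domains' or 's60_clusters'")
    if count <= 0:
        raise ValueError("denominator count must be positive")
    fractions = np.array([len(s) / count for s in per_pos])
    return HeatmapFractions(site_type, denominator, count, fractions,
                            [colour_bin(f) for f in fractions])


# ---------------------------------------------------------------------------
# Hubs
# ---------------------------------------------------------------------------

def flag_hub_superfamilies(interaction_counts: Mapping[str, int],
                           membership: Mapping[str, str],
                           min_interactions: int = 10) -> set[str]:
    """Superfamilies where at least one member has >= min_interactions
    physical interaction partners (counts already mapped down from the
    parent proteins)."""
    hubs: set[str] = set()
    for domain_id, count in interaction_counts.items():
        sf = membership.get(domain_id)
        if sf is not None and count >= min_interactions:
            hubs.add(sf)
    return hubs
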