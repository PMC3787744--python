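"""Preferential colocation of functional sites across s60 clusters.

A superfamily shows preferential colocation of a site type when at least one
representative position carries a site in a large fraction of its s60
clusters.  The statistic reported is that maximum fraction, with the
denominator restricted to clusters that possess at least one annotation of
the same site type; superfamilies with fewer than 10 such clusters are
flagged not-included so that the fractions cannot be driven by
under-sampling (50% of 2 clusters is a single cluster).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .pairwise_align import StructuralAlignment, similarity_score
from .site_mapping import (
    Aligner,
    CoverageResult,
    RepresentativeProfile,
    build_profile,
    coverage,
)
from .structure_io import DomainStructure, SiteAnnotation


@dataclass
class ColocationResult:
    superfamily_id: str
    site_type: str
    n_clusters_with_data: int
    max_fraction: float
    argmax_positions: set[int]
    included: bool


def colocation_statistic(profile: RepresentativeProfile, site_type: str,
                         min_clusters: int = 10) -> ColocationResult:
    """Maximum fraction of s60 clusters sharing a site at one position.

    A cluster "has a site at position p" iff at least one of its member
    domains contributes at p.  The denominator counts clusters with at
    least one annotation of this site type -- including clusters whose
    annotated residues all fell on gaps (they have data; they simply hit no
    position).  ``included`` is False when fewer than ``min_clusters``
    clusters have data.
    """
    if profile.s60_assignment is None:
        raise ValueError("profile has no s60 assignment")
    clusters_with_data = {
        profile.s60_assignment[d]
        for d in profile.annotated_domains.get(site_type, set())
    }
    n_data = len(clusters_with_data)
    max_fraction = 0.0
    argmax: set[int] = set()
    if n_data > 0:
        per_pos = profile.cluster_contributors(site_type)
        for p, hit in enumerate(per_pos):
            frac = len(hit & clusters_with_data) / n_data
            if frac > max_fraction:
                max_fraction, argmax = frac, {p}
            elif frac == max_fraction and frac > 0:
                argmax.add(p)
    return ColocationResult(
        superfamily_id=profile.superfamily_id, site_type=site_type,
        n_clusters_with_data=n_data, max_fraction=max_fraction,
        argmax_positions=argmax, included=n_data >= min_clusters,
    )


def select_family_representative(members: Mapping[str, DomainStructure],
                                 aligner: Aligner) -> str:
    """Representative of a functional family: the member with maximal
    cumulative similarity to all other members (ties: smallest id)."""
    ids = sorted(members)
    if len(ids) == 1:
        return ids[0]
    totals = {m: 0.0 for m in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            da, db = members[a], members[b]
            sc = similarity_score(aligner(da, db), da.length, db.length)
            totals[a] += sc
            totals[b] += sc
    return max(ids, key=lambda m: totals[m])  # first max: smallest id wins ties


def subfamily_coverage(family_id: str,
                       members: Mapping[str, DomainStructure],
                       aligner: Aligner,
                       annotations: Iterable[SiteAnnotation],
                       site_type: str,
                       min_rep_length: int = 100,
                       dominance: float = 0.5,
                       apply_filters: bool = True) -> CoverageResult:
    """Coverage scoped to a functional family and its own representative.

    Identical protocol to superfamily coverage, run over the family's
    members only.  A single-member family is computed trivially against
    itself and flagged ``single_member``.
    """
    if not members:
        raise ValueError("family has no members")
    rep_id = select_family_representative(members, aligner)
    rep = members[rep_id]
    alignments: dict[str, StructuralAlignment] = {}
    family_annotations = [a for a in annotations if a.site_type == site_type
                          and a.domain_id in members]
    for ann in family_annotations:
        if ann.domain_id != rep_id and ann.domain_id not in alignments:
            alignments[ann.domain_id] = aligner(members[ann.domain_id], rep)
    profile = build_profile(family_id, members, rep_id, alignments,
                            family_annotations)
    result = coverage(profile, site_type, min_rep_length=min_rep_length,
                      dominance=dominance,
                      apply_length_filter=apply_filters,
                      apply_dominance_filter=apply_filters)
    result.single_member = len(members) == 1
    return result
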