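"""Seeded synthetic superfamilies with planted ground truth.

The generator emulates the data model the pipeline consumes: a superfamily
is a set of CA-trace domains derived from one compact self-avoiding template
chain.  Members are grouped into sequence clusters; each cluster carries a
rigid transform, cluster-level coordinate noise (shared by its members) and
per-member noise, and sequences mutated to hit within/between-cluster
identity targets.  Functional sites are planted in the template frame:

* a *preferred* site (a spatially compact footprint) used by a controlled
  fraction f of clusters -- the signal the colocation statistic must recover;
* *scattered* cluster-specific sites at random template locations -- the
  background that drives coverage up without colocation;
* optionally, sites on *embellishments* (inserted surface loops), present
  only in embellished members.

Structural diversity is planted by giving a subset of clusters an
alternative conformation whose C-terminal part is regrown as an
independent outward walk; the displacement is resampled until the pairwise
normalised RMSD between the two conformational groups clears the 9 A
clustering cutoff with margin.

All randomness flows from one top-level seed through
``numpy.random.SeedSequence`` spawning, so any subset of superfamilies
regenerates identically.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .family_clustering import ClusterSet
from .structure_io import DomainStructure, ResidueRef, SiteAnnotation

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Ground-truth parameters for one site type."""

    site_type: str = "protein_protein"
    footprint: int = 12            # residues in the preferred site
    preferred_fraction: float = 0.8  # fraction f of clusters using it
    scatter_sites: int = 1         # cluster-specific random sites per cluster
    scatter_footprint: int = 6     # residues per scattered site
    core_only: bool = False        # place sites on the conformationally
    #                                invariant core (before the hinge pivot)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic superfamily cohort."""

    n_superfamilies: int = 1
    clusters_per_superfamily: int = 12
    members_per_cluster: int = 2
    template_length: int = 120
    coord_noise_within: float = 0.5    # A, per-member Gaussian CA noise
    coord_noise_between: float = 1.0   # A, cluster-level shared perturbation
    seq_identity_within: float = 0.90  # target pairwise identity inside a cluster
    seq_identity_between: float = 0.35  # target identity between cluster seeds
    embellishment_prob: float = 0.0    # per-member insertion probability
    embellishment_length: tuple[int, int] = (8, 15)
    embellishment_shared: bool = True  # one insertion geometry per superfamily
    embellishment_site_prob: float = 0.0  # chance an embellishment carries a site
    hinge_fraction: float = 0.0        # fraction of clusters with a refolded tail
    hinge_pivot_fraction: float = 0.6  # chain fraction where the tail detaches;
    #                                    the shared part stays the majority so
    #                                    superposition anchors on it
    planted_sites: tuple[PlantedSiteSpec, ...] = (PlantedSiteSpec(),)
    ligand_distance: float = 4.0       # A, proximity cutoff for derived sites
    interaction_count_lambda: float = 3.0  # Poisson mean of per-domain hub counts

    def __post_init__(self) -> None:
        for p in (self.seq_identity_within, self.seq_identity_between,
                  self.embellishment_prob, self.embellishment_site_prob,
                  self.hinge_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities and fractions must lie in [0, 1]")
        for s in self.planted_sites:
            if not 0.0 <= s.preferred_fraction <= 1.0:
                raise ValueError("preferred_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the pipeline's outputs."""

    superfamily_id: str
    template: DomainStructure
    cluster_of: dict[str, int]
    member_to_template: dict[str, list[int | None]]
    preferred_positions: dict[str, set[int]]  # site_type -> template positions
    preferred_clusters: dict[str, set[int]]   # site_type -> clusters using them
    planted_positions: dict[str, dict[str, set[int]]]  # type -> member -> template pos
    embellishment_positions: dict[str, set[int]]  # member -> member positions
    diverse: bool
    hinged_clusters: set[int]
    interaction_counts: dict[str, int]

    def union_template_positions(self, site_type: str) -> set[int]:
        out: set[int] = set()
        for positions in self.planted_positions.get(site_type, {}).values():
            out |= positions
        return out

    def union_footprint_fraction(self, site_type: str) -> float:
        return len(self.union_template_positions(site_type)) / self.template.length


@dataclass
class SyntheticSuperfamily:
    superfamily_id: str
    domains: dict[str, DomainStructure]
    annotations: list[SiteAnnotation]
    family_table: pd.DataFrame
    truth: GroundTruth

    def s60_clusters(self) -> ClusterSet:
        """The planted cluster partition as a ClusterSet."""
        by_cluster: dict[int, set[str]] = {}
        for d, k in self.truth.cluster_of.items():
            by_cluster.setdefault(k, set()).add(d)
        return ClusterSet(kind="s60",
                          clusters=[by_cluster[k] for k in sorted(by_cluster)],
                          parameter=0.60)


# ---------------------------------------------------------------------------
# Template chain
# ---------------------------------------------------------------------------

def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_template(length: int, seed_or_rng: int | np.random.Generator,
                  max_restarts: int = 100) -> DomainStructure:
    """A compact self-avoiding CA trace with 3.8 +- 0.01 A virtual bonds.

    Consecutive CAs are bonded at 3.8 A (jitter 0.01 A); non-bonded CA pairs
    keep a clearance above 2 A.  A gentle pull toward the running centroid
    keeps the chain globular.  Deterministic for a fixed seed.
    """
    if length < 3:
        raise ValueError("template length must be >= 3")
    rng = (np.random.default_rng(seed_or_rng)
           if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng)
    for _ in range(max_restarts):
        coords = np.zeros((length, 3))
        direction = _random_unit(rng)
        ok = True
        for i in range(1, length):
            placed = False
            for _attempt in range(60):
                centroid = coords[:i].mean(axis=0)
                pull = centroid - coords[i - 1]
                norm = np.linalg.norm(pull)
                pull = pull / norm if norm > 1e-9 else 0.0
                cand = 0.8 * direction + 1.1 * rng.normal(size=3) + 0.25 * pull
                cand /= np.linalg.norm(cand)
                bond = 3.8 + rng.uniform(-0.01, 0.01)
                pos = coords[i - 1] + bond * cand
                if i >= 2:
                    d = np.linalg.norm(coords[: i - 1] - pos, axis=1)
                    if d.min() <= 2.1:
                        continue
                coords[i] = pos
                direction = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            seq = "".join(rng.choice(list(_AA), size=length))
            refs = [ResidueRef("A", i + 1, "") for i in range(length)]
            return DomainStructure("template", refs, seq, coords)
    raise RuntimeError(f"self-avoiding template failed after {max_restarts} restarts")


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate a deterministic fraction ``rate`` of positions to new residues."""
    n = len(seq)
    n_mut = int(round(rate * n))
    if n_mut == 0:
        return seq
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in _AA if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _compact_footprint(template: DomainStructure, size: int,
                       rng: np.random.Generator,
                       exclude: set[int] | None = None) -> set[int]:
    """A spatially compact set of template positions around a random centre.

    Positions in ``exclude`` are avoided (used to keep cluster-specific
    scattered sites off the shared preferred footprint, which is what makes
    them subfamily-specific)."""
    exclude = exclude or set()
    allowed = [i for i in range(template.length) if i not in exclude]
    centre = int(allowed[rng.integers(len(allowed))])
    d = np.linalg.norm(template.coords - template.coords[centre], axis=1)
    order = [int(i) for i in np.argsort(d, kind="stable") if int(i) not in exclude]
    return set(order[:size])


def _grow_chain(prefix: np.ndarray, n_new: int, rng: np.random.Generator,
                direction: np.ndarray, clearance: float = 2.1,
                pull_weight: float = 0.25,
                max_attempts: int = 60) -> np.ndarray | None:
    """Extend a CA chain by ``n_new`` residues with 3.8 A bonds, keeping
    every new atom at least ``clearance`` from all non-bonded atoms.
    ``pull_weight`` biases growth toward (positive) or away from (negative)
    the running centroid.  Returns None if growth stalls (caller retries)."""
    coords = list(prefix)
    for _ in range(n_new):
        placed = False
        for _attempt in range(max_attempts):
            centroid = np.mean(coords, axis=0)
            pull = centroid - coords[-1]
            norm = np.linalg.norm(pull)
            pull = pull / norm if norm > 1e-9 else 0.0
            cand = 0.8 * direction + 1.1 * rng.normal(size=3) + pull_weight * pull
            cand /= np.linalg.norm(cand)
            bond = 3.8 + rng.uniform(-0.01, 0.01)
            pos = coords[-1] + bond * cand
            d = np.linalg.norm(np.asarray(coords[:-1]) - pos, axis=1)
            if len(coords) > 1 and d.min() <= clearance:
                continue
            coords.append(pos)
            direction = cand
            placed = True
            break
        if not placed:
            return None
    return np.asarray(coords)


def _refold_tail(coords: np.ndarray, pivot_index: int,
                 rng: np.random.Generator, min_rmsd: float = 16.0,
                 max_restarts: int = 200) -> np.ndarray:
    """An alternative conformation: regrow the chain beyond ``pivot_index``
    as an independent self-avoiding walk seeded away from the core.

    Unlike a rigid hinge rotation, the regrown tail is incoherent with the
    original one, so no rigid superposition of two conformers can absorb
    the tail displacement: the optimal fit anchors on the shared core.
    Candidate tails are resampled until the optimally superposed
    whole-domain RMSD between the two conformers is at least ``min_rmsd``.
    The margin over the 9 A structural clustering cutoff is deliberately
    generous: an aligner is free to re-pair tail residues off the diagonal
    and to trade aligned pairs for gaps, both of which shrink the measured
    normalised RMSD relative to the fixed-correspondence RMSD."""
    from .pairwise_align import kabsch_superpose

    n_tail = len(coords) - pivot_index
    u = coords[pivot_index] - coords[:pivot_index].mean(axis=0)
    u = u / np.linalg.norm(u)
    for _ in range(max_restarts):
        out = _grow_chain(coords[:pivot_index], n_tail, rng,
                          direction=u + 0.8 * rng.normal(size=3),
                          pull_weight=-0.4)  # grow outward, away from the core
        if out is None:
            continue
        _, _, rmsd = kabsch_superpose(coords, out)
        if rmsd >= min_rmsd:
            return out
    raise RuntimeError("tail refolding failed to reach the displacement target")


def _embellishment_loop(before: np.ndarray, after: np.ndarray,
                        centroid: np.ndarray, length: int,
                        rng: np.random.Generator) -> np.ndarray:
    """A surface loop bulging outward between two anchor CAs."""
    u = (before + after) / 2.0 - centroid
    u = u / np.linalg.norm(u)
    height = 1.4 * length
    pts = np.empty((length, 3))
    for i in range(length):
        t = (i + 1) / (length + 1)
        base = (1 - t) * before + t * after
        pts[i] = base + u * height * np.sin(np.pi * t) + rng.normal(scale=0.3, size=3)
    return pts


# ---------------------------------------------------------------------------
# Superfamily generation
# ---------------------------------------------------------------------------

def make_superfamily(config: SyntheticConfig, seed: int | np.random.SeedSequence,
                     superfamily_id: str = "SF0000") -> SyntheticSuperfamily:
    """Generate one superfamily with full ground-truth bookkeeping."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    length = config.template_length
    template = make_template(length, np.random.default_rng(ss.spawn(1)[0]))

    n_clusters = config.clusters_per_superfamily
    hinge_pivot = int(config.hinge_pivot_fraction * length)
    # planted preferred sites (template frame) and the clusters using them
    preferred_positions: dict[str, set[int]] = {}
    preferred_clusters: dict[str, set[int]] = {}
    # core_only placement keeps a safety margin before the pivot so that
    # site-bearing residues sit well inside the rigid, superposition-anchoring
    # part of the chain
    tail = set(range(int(0.75 * hinge_pivot), length))
    for spec in config.planted_sites:
        preferred_positions[spec.site_type] = _compact_footprint(
            template, spec.footprint, rng,
            exclude=tail if spec.core_only else None)
        n_using = int(round(spec.preferred_fraction * n_clusters))
        preferred_clusters[spec.site_type] = set(
            rng.choice(n_clusters, size=n_using, replace=False).tolist())

    # clusters with a refolded tail define the planted structural diversity
    n_hinged = int(round(config.hinge_fraction * n_clusters))
    hinged = set(rng.choice(n_clusters, size=n_hinged, replace=False).tolist()) \
        if n_hinged else set()
    hinged_coords = (_refold_tail(template.coords, hinge_pivot, rng)
                     if hinged else None)

    # one shared embellishment geometry per superfamily (if enabled)
    emb_len = int(rng.integers(config.embellishment_length[0],
                               config.embellishment_length[1] + 1))
    emb_at = int(rng.integers(10, length - 10)) if length > 20 else length // 2

    cluster_mut = (1.0 - config.seq_identity_between) / 2.0
    member_mut = (1.0 - config.seq_identity_within) / 2.0

    domains: dict[str, DomainStructure] = {}
    annotations: list[SiteAnnotation] = []
    truth = GroundTruth(
        superfamily_id=superfamily_id, template=template, cluster_of={},
        member_to_template={}, preferred_positions=preferred_positions,
        preferred_clusters=preferred_clusters,
        planted_positions={s.site_type: {} for s in config.planted_sites},
        embellishment_positions={}, diverse=bool(hinged),
        hinged_clusters=hinged, interaction_counts={},
    )
    rows = []
    for k in range(n_clusters):
        crng = np.random.default_rng(ss.spawn(1)[0])
        base = hinged_coords if k in hinged else template.coords
        cluster_coords = base + crng.normal(scale=config.coord_noise_between,
                                            size=base.shape)
        cluster_seq = _mutate(template.sequence, cluster_mut, crng)
        scatter: dict[str, set[int]] = {}
        for spec in config.planted_sites:
            pos: set[int] = set()
            avoid = set(preferred_positions[spec.site_type])
            if spec.core_only:
                avoid |= tail
            for _ in range(spec.scatter_sites):
                pos |= _compact_footprint(template, spec.scatter_footprint, crng,
                                          exclude=avoid)
            scatter[spec.site_type] = pos
        for m in range(config.members_per_cluster):
            member_id = f"{superfamily_id}_c{k:02d}m{m}"
            coords = cluster_coords + crng.normal(scale=config.coord_noise_within,
                                                  size=cluster_coords.shape)
            seq = _mutate(cluster_seq, member_mut, crng)
            to_template: list[int | None] = list(range(length))
            emb_member: set[int] = set()
            if config.embellishment_prob and crng.random() < config.embellishment_prob:
                at = emb_at if config.embellishment_shared else int(
                    crng.integers(10, length - 10))
                ln = emb_len if config.embellishment_shared else int(
                    crng.integers(config.embellishment_length[0],
                                  config.embellishment_length[1] + 1))
                loop = _embellishment_loop(coords[at - 1], coords[at],
                                           coords.mean(axis=0), ln, crng)
                coords = np.vstack([coords[:at], loop, coords[at:]])
                seq = seq[:at] + "".join(crng.choice(list(_AA), size=ln)) + seq[at:]
                to_template = list(range(at)) + [None] * ln + list(range(at, length))
                emb_member = set(range(at, at + ln))
            # random rigid placement: downstream statistics are superposition-invariant
            rot = _rotation_matrix(_random_unit(crng), crng.uniform(0, 2 * np.pi))
            coords = coords @ rot.T + crng.uniform(-50, 50, size=3)
            refs = [ResidueRef("A", i + 1, "") for i in range(len(seq))]
            dom = DomainStructure(member_id, refs, seq, coords,
                                  superfamily_id=superfamily_id,
                                  s60_cluster_id=f"s60_{k:03d}")
            domains[member_id] = dom
            truth.cluster_of[member_id] = k
            truth.member_to_template[member_id] = to_template
            truth.embellishment_positions[member_id] = emb_member
            truth.interaction_counts[member_id] = int(
                crng.poisson(config.interaction_count_lambda))
            template_to_member = {t: i for i, t in enumerate(to_template)
                                  if t is not None}
            for spec in config.planted_sites:
                site_positions: set[int] = set()
                if k in preferred_clusters[spec.site_type]:
                    site_positions |= preferred_positions[spec.site_type]
                site_positions |= scatter[spec.site_type]
                member_positions = {template_to_member[t] for t in site_positions}
                resset = {refs[p] for p in member_positions}
                evidence = {f"planted_{spec.site_type}"}
                if emb_member and config.embellishment_site_prob and \
                        crng.random() < config.embellishment_site_prob:
                    emb_sorted = sorted(emb_member)
                    mid = len(emb_sorted) // 2
                    picked = emb_sorted[max(0, mid - 3): mid + 3]
                    resset |= {refs[p] for p in picked}
                    member_positions |= set(picked)
                    evidence.add("planted_embellishment")
                if resset:
                    annotations.append(SiteAnnotation(
                        member_id, spec.site_type, resset, evidence))
                truth.planted_positions[spec.site_type][member_id] = site_positions
            rows.append({"domain_id": member_id, "superfamily_id": superfamily_id,
                         "s60_cluster_id": f"s60_{k:03d}",
                         "funfam_id": f"{superfamily_id}_ff{k:03d}"})
    table = pd.DataFrame(rows, columns=["domain_id", "superfamily_id",
                                        "s60_cluster_id", "funfam_id"])
    return SyntheticSuperfamily(superfamily_id, domains, annotations, table, truth)


def make_cohort(config: SyntheticConfig, seed: int,
                prefix: str = "SF") -> list[SyntheticSuperfamily]:
    """Generate ``config.n_superfamilies`` superfamilies from one seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_superfamilies)
    return [make_superfamily(config, child, f"{prefix}{i:04d}")
            for i, child in enumerate(children)]


# ---------------------------------------------------------------------------
# Ligand-proximity sites
# ---------------------------------------------------------------------------

def sites_from_pseudo_ligand(domain: DomainStructure, ligand_coords: np.ndarray,
                             cutoff: float = 4.0,
                             site_type: str = "small_ligand",
                             evidence_id: str = "pseudo_ligand") -> SiteAnnotation:
    """Annotate residues whose CA lies within ``cutoff`` of any ligand point.

    Mirrors the distance rule used by interaction databases to call binding
    residues around a bound ligand (4 A by default).
    """
    ligand = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    if ligand.size == 0:
        raise ValueError("ligand_coords must be non-empty")
    d = cdist(domain.coords, ligand)
    hit = np.nonzero((d <= cutoff).any(axis=1))[0]
    residues = {domain.refs[i] for i in hit}
    return SiteAnnotation(domain.domain_id, site_type, residues, {evidence_id})


# ---------------------------------------------------------------------------
# Conservation-study families (sequence-only)
# ---------------------------------------------------------------------------

@dataclass
class ConservationFamilyTruth:
    functional_columns: set[int]
    fragment_ids: set[str]
    functional_residues: dict[str, set[int]]  # row id -> functional columns present


def make_conservation_family(seed: int | np.random.SeedSequence,
                             family_id: str = "fam0",
                             n_sequences: int = 12,
                             length: int = 120,
                             n_functional_columns: int = 10,
                             functional_conserved: bool = True,
                             conserved_mutation_rate: float = 0.05,
                             background_identity: float = 0.5,
                             fragment_fraction: float = 0.0,
                             fragment_length_fraction: float = 0.5,
                             family_kind: str = "funfam",
                             ):
    """A synthetic functional-family MSA with planted functional columns.

    When ``functional_conserved`` is true the functional columns are highly
    conserved (per-row mutation probability ``conserved_mutation_rate``);
    otherwise functional residues sit at random columns unrelated to
    conservation (the null case).  Background columns share a consensus
    residue with probability ``background_identity`` and are random
    otherwise.  A ``fragment_fraction`` of rows are truncated to a
    contiguous window of ``fragment_length_fraction`` of the columns (the
    rest gapped), emulating partial sequences.

    Returns ``(FamilyAlignment, ConservationFamilyTruth)``.
    """
    from .conservation import GAP, FamilyAlignment

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    consensus = rng.choice(list(_AA), size=length)
    functional = set(rng.choice(length, size=n_functional_columns,
                                replace=False).tolist())
    ids = [f"{family_id}_s{i:02d}" for i in range(n_sequences)]
    n_fragments = int(round(fragment_fraction * n_sequences))
    fragment_ids = set(rng.choice(ids, size=n_fragments, replace=False).tolist()) \
        if n_fragments else set()
    rows: list[str] = []
    truth_res: dict[str, set[int]] = {}
    for rid in ids:
        row = []
        for c in range(length):
            conserved_col = functional_conserved and c in functional
            rate = conserved_mutation_rate if conserved_col \
                else 1.0 - background_identity
            if rng.random() < rate:
                choices = [a for a in _AA if a != consensus[c]]
                row.append(choices[rng.integers(len(choices))])
            else:
                row.append(consensus[c])
        if rid in fragment_ids:
            win = int(round(fragment_length_fraction * length))
            start = int(rng.integers(0, length - win + 1))
            row = [GAP] * start + row[start:start + win] + [GAP] * (length - start - win)
        rows.append("".join(row))
        truth_res[rid] = {c for c in functional if rows[-1][c] != GAP}
    alignment = FamilyAlignment(family_id, ids, rows, family_kind=family_kind)
    return alignment, ConservationFamilyTruth(functional, fragment_ids, truth_res)
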