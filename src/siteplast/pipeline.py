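"""End-to-end orchestration: from domains + annotations + family tables to
coverage, colocation, structural-diversity and enrichment summaries.

`analyse_superfamily` is the in-memory heart shared by the command-line
stages, the synthetic-recovery studies and the tests; `run_all` wires it to
the on-disk layout and writes the summary tables plus a run manifest.

Superfamily-level exclusions mirror the dataset filters: superfamilies made
of a single s60 cluster or with no functional-site data are excluded up
front; the per-site-type coverage filters (representative shorter than 100
residues, single-domain dominance above 50%) are applied inside the
coverage computation and surfaced in the exclusion ledger.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .colocation import ColocationResult, colocation_statistic
from .conservation import (
    FamilyAlignment,
    conservation_scores,
    conserved_to_sites,
    overlap_proportion,
    remove_fragment_rows,
)
from .family_clustering import (
    ClusterSet,
    cluster_s60,
    cluster_structures,
    compute_nrmsd_pairs,
    is_structurally_diverse,
)
from .pairwise_align import AlignParams, CachingAligner, StructuralAlignment
from .site_mapping import (
    CoverageResult,
    RepresentativeProfile,
    SingleClusterError,
    build_profile,
    coverage,
    cluster_representatives,
    flag_hub_superfamilies,
    select_representative,
)
from .stats import (
    EnrichmentResult,
    average_by_superfamily,
    compare_diverse_vs_similar,
    enrichment,
    enrichment_test,
    high_coverage_proportion,
)
from .structure_io import (
    DomainStructure,
    SiteAnnotation,
    read_alignment_tsv,
    read_domain_pdb,
    read_family_table,
    read_interaction_counts,
    read_site_annotations,
    write_domain_pdb,
    write_family_table,
    write_interaction_counts,
    write_profile_pdb,
    write_site_annotations,
)
from .synthetic_data import SyntheticSuperfamily

logger = logging.getLogger(__name__)

DEFAULT_SITE_TYPES = ("catalytic", "protein_protein", "nucleic_acid", "small_ligand")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run (defaults are the published
    protocol's values)."""

    input_dir: str = "."
    output_dir: str = "run"
    min_rep_length: int = 100
    dominance: float = 0.5
    colocation_min_clusters: int = 10
    s60_identity: float = 0.60
    nrmsd_cutoffs: tuple[float, ...] = (9.0, 5.0)
    conservation_threshold: float = 0.7
    fragment_fraction: float = 0.8
    drop_fragments: bool = False
    hub_min_interactions: int = 10
    site_types: tuple[str, ...] = DEFAULT_SITE_TYPES
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("nrmsd_cutoffs", "site_types"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["nrmsd_cutoffs"] = list(self.nrmsd_cutoffs)
        data["site_types"] = list(self.site_types)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class SuperfamilyAnalysis:
    """Everything the pipeline derives for one superfamily."""

    superfamily_id: str
    excluded: bool = False
    exclusion_reason: str = "none"
    representative_id: str = ""
    s60: ClusterSet | None = None
    profile: RepresentativeProfile | None = None
    coverages: dict[str, CoverageResult] = field(default_factory=dict)
    colocations: dict[str, ColocationResult] = field(default_factory=dict)
    structural_clusters: dict[float, ClusterSet] = field(default_factory=dict)
    diverse: dict[float, bool] = field(default_factory=dict)


def analyse_superfamily(superfamily_id: str,
                        domains: Mapping[str, DomainStructure],
                        annotations: Sequence[SiteAnnotation],
                        config: RunConfig | None = None,
                        s60: ClusterSet | None = None,
                        aligner: CachingAligner | None = None,
                        site_types: Sequence[str] | None = None,
                        ) -> SuperfamilyAnalysis:
    """Run the per-superfamily protocol in memory.

    Stages: s60 clustering (unless a planted/known partition is supplied) ->
    representative selection -> member alignment -> site mapping -> coverage
    -> colocation -> structural clustering of the s60 representatives at
    each nRMSD cutoff.
    """
    config = config or RunConfig()
    aligner = aligner or CachingAligner(AlignParams())
    site_types = tuple(site_types or config.site_types)
    result = SuperfamilyAnalysis(superfamily_id=superfamily_id)
    result.s60 = s60 or cluster_s60(domains.values(), threshold=config.s60_identity)

    if not annotations:
        result.excluded = True
        result.exclusion_reason = "no_site_data"
        return result
    try:
        rep_id = select_representative(domains, result.s60, aligner)
    except SingleClusterError:
        result.excluded = True
        result.exclusion_reason = "single_s60_cluster"
        return result
    result.representative_id = rep_id
    rep = domains[rep_id]

    alignments: dict[str, StructuralAlignment] = {}
    annotated = {a.domain_id for a in annotations}
    for member_id in sorted(annotated):
        if member_id != rep_id:
            alignments[member_id] = aligner(domains[member_id], rep)
    result.profile = build_profile(superfamily_id, domains, rep_id, alignments,
                                   annotations, s60_clusters=result.s60)
    for st in site_types:
        result.coverages[st] = coverage(
            result.profile, st, min_rep_length=config.min_rep_length,
            dominance=config.dominance)
        result.colocations[st] = colocation_statistic(
            result.profile, st, min_clusters=config.colocation_min_clusters)

    # structural diversity over the s60 cluster representatives
    reps = cluster_representatives(result.s60)
    nrmsd = compute_nrmsd_pairs([domains[r] for r in reps], aligner)
    for cutoff in config.nrmsd_cutoffs:
        cs = cluster_structures(reps, nrmsd, cutoff=cutoff)
        result.structural_clusters[cutoff] = cs
        result.diverse[cutoff] = is_structurally_diverse(cs)
    return result


def analyse_synthetic(sf: SyntheticSuperfamily, config: RunConfig | None = None,
                      aligner: CachingAligner | None = None,
                      use_planted_clusters: bool = True,
                      site_types: Sequence[str] | None = None,
                      ) -> SuperfamilyAnalysis:
    """Convenience wrapper: run the protocol on one synthetic superfamily."""
    return analyse_superfamily(
        sf.superfamily_id, sf.domains, sf.annotations, config=config,
        s60=sf.s60_clusters() if use_planted_clusters else None,
        aligner=aligner, site_types=site_types)


def exclusion_ledger(analyses: Iterable[SuperfamilyAnalysis],
                     site_type: str) -> dict[str, str]:
    """Per superfamily, the first exclusion rule it hit for one site type
    ("none" for superfamilies retained in the coverage dataset)."""
    ledger: dict[str, str] = {}
    for a in analyses:
        if a.excluded:
            ledger[a.superfamily_id] = a.exclusion_reason
            continue
        cov = a.coverages.get(site_type)
        ledger[a.superfamily_id] = cov.exclusion_reason if cov and cov.excluded \
            else "none"
    counts: dict[str, int] = {}
    for reason in ledger.values():
        counts[reason] = counts.get(reason, 0) + 1
    logger.info("exclusion accounting (%s): %s", site_type,
                {k: counts[k] for k in sorted(counts)})
    return ledger


# ---------------------------------------------------------------------------
# Enrichment over functional families
# ---------------------------------------------------------------------------

@dataclass
class FamilyEnrichment:
    family_id: str
    site_type: str
    enrichment: EnrichmentResult
    overlap_fraction: float
    overlap_defined: bool


def analyse_family_conservation(alignment: FamilyAlignment,
                                domains: Mapping[str, DomainStructure],
                                annotations: Sequence[SiteAnnotation],
                                config: RunConfig | None = None,
                                site_types: Sequence[str] | None = None,
                                ) -> tuple[list[SiteAnnotation], list[FamilyEnrichment]]:
    """Conservation -> conserved sites -> overlap and enrichment for one family.

    Returns the conserved-site annotations (for downstream superfamily
    mapping) and one enrichment record per requested site type.
    """
    config = config or RunConfig()
    site_types = tuple(site_types or config.site_types)
    if config.drop_fragments:
        alignment = remove_fragment_rows(alignment, config.fragment_fraction)
    profile = conservation_scores(alignment, threshold=config.conservation_threshold)
    conserved_sites = conserved_to_sites(profile, alignment, domains)
    member_ids = [i for i in alignment.ids if i in domains]
    all_residues = {(d, ref) for d in member_ids for ref in domains[d].refs}
    conserved_set = {(ann.domain_id, ref) for ann in conserved_sites
                     for ref in ann.residues}
    out: list[FamilyEnrichment] = []
    for st in site_types:
        functional = {(a.domain_id, ref) for a in annotations
                      if a.site_type == st and a.domain_id in domains
                      for ref in a.residues if ref in domains[a.domain_id]}
        if not all_residues:
            continue
        enr = enrichment(conserved_set, functional, all_residues,
                         family_id=alignment.family_id)
        ovl = overlap_proportion(conserved_sites,
                                 [a for a in annotations if a.domain_id in domains],
                                 st)
        out.append(FamilyEnrichment(alignment.family_id, st, enr,
                                    ovl.fraction, ovl.defined))
    return conserved_sites, out


# ---------------------------------------------------------------------------
# File-based run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunInputs:
    domains: dict[str, DomainStructure]
    annotations: list[SiteAnnotation]
    family_table: pd.DataFrame
    interaction_counts: dict[str, int]
    precomputed: list[StructuralAlignment]
    family_alignments: list[FamilyAlignment]
    digests: dict[str, str]


def load_inputs(input_dir: str | Path) -> RunInputs:
    """Read the standard input layout.

    Expected under ``input_dir``: ``families.tsv`` (membership table),
    ``pdb/<domain_id>.pdb`` structures, ``sites.tsv`` annotations; optional
    ``interactions.tsv``, ``alignments/*.tsv`` precomputed alignments and
    ``msa/*.fasta`` functional-family alignments.
    """
    root = Path(input_dir)
    digests: dict[str, str] = {}
    table_path = root / "families.tsv"
    if not table_path.exists():
        raise FileNotFoundError(f"missing family table {table_path}")
    table = read_family_table(table_path)
    digests["families.tsv"] = _sha256(table_path)
    domains: dict[str, DomainStructure] = {}
    for row in table.itertuples(index=False):
        pdb = root / "pdb" / f"{row.domain_id}.pdb"
        if not pdb.exists():
            raise FileNotFoundError(
                f"stage align: structure for domain {row.domain_id} not found "
                f"at {pdb}")
        dom = read_domain_pdb(pdb, row.domain_id, row.superfamily_id)
        dom.s60_cluster_id = row.s60_cluster_id or None
        domains[row.domain_id] = dom
        digests[f"pdb/{row.domain_id}.pdb"] = _sha256(pdb)
    sites_path = root / "sites.tsv"
    annotations: list[SiteAnnotation] = []
    if sites_path.exists():
        annotations, _report = read_site_annotations(sites_path, domains)
        digests["sites.tsv"] = _sha256(sites_path)
    counts: dict[str, int] = {}
    ipath = root / "interactions.tsv"
    if ipath.exists():
        counts = read_interaction_counts(ipath)
        digests["interactions.tsv"] = _sha256(ipath)
    precomputed: list[StructuralAlignment] = []
    adir = root / "alignments"
    if adir.is_dir():
        for f in sorted(adir.glob("*.tsv")):
            precomputed.append(read_alignment_tsv(f, domains))
            digests[f"alignments/{f.name}"] = _sha256(f)
    family_alignments: list[FamilyAlignment] = []
    mdir = root / "msa"
    if mdir.is_dir():
        for f in sorted(mdir.glob("*.fasta")):
            family_alignments.append(FamilyAlignment.from_fasta(f))
            digests[f"msa/{f.name}"] = _sha256(f)
    return RunInputs(domains, annotations, table, counts, precomputed,
                     family_alignments, digests)


def write_synthetic_inputs(superfamilies: Sequence[SyntheticSuperfamily],
                           out_dir: str | Path) -> Path:
    """Write synthetic superfamilies in the exact layout :func:`load_inputs`
    reads, plus ground-truth TSVs for recovery scoring."""
    root = Path(out_dir)
    (root / "pdb").mkdir(parents=True, exist_ok=True)
    tables, annotations, counts = [], [], {}
    truth_rows = []
    for sf in superfamilies:
        tables.append(sf.family_table)
        annotations.extend(sf.annotations)
        counts.update(sf.truth.interaction_counts)
        for dom in sf.domains.values():
            write_domain_pdb(dom, root / "pdb" / f"{dom.domain_id}.pdb")
        for st, positions in sf.truth.preferred_positions.items():
            for p in sorted(positions):
                truth_rows.append({"superfamily_id": sf.superfamily_id,
                                   "site_type": st, "template_position": p,
                                   "kind": "preferred"})
        for st in sf.truth.planted_positions:
            for p in sorted(sf.truth.union_template_positions(st)):
                truth_rows.append({"superfamily_id": sf.superfamily_id,
                                   "site_type": st, "template_position": p,
                                   "kind": "union"})
    write_family_table(pd.concat(tables, ignore_index=True), root / "families.tsv")
    write_site_annotations(annotations, root / "sites.tsv")
    write_interaction_counts(counts, root / "interactions.tsv")
    pd.DataFrame(truth_rows, columns=["superfamily_id", "site_type",
                                      "template_position", "kind"]
                 ).to_csv(root / "ground_truth.tsv", sep="\t", index=False)
    return root


def _planted_clusters(table: pd.DataFrame, sf: str) -> ClusterSet | None:
    sub = table[table["superfamily_id"] == sf]
    if (sub["s60_cluster_id"] == "").any():
        return None
    groups = sub.groupby("s60_cluster_id")["domain_id"].apply(set)
    return ClusterSet(kind="s60", clusters=[groups[k] for k in sorted(groups.index)],
                      parameter=0.60)


def run_all(config: RunConfig) -> Path:
    """Run every stage over an input directory; returns the output directory.

    Deterministic for fixed config and inputs; summary tables are written
    sorted so reruns are byte-identical.
    """
    inputs = load_inputs(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    aligner = CachingAligner(AlignParams())
    aligner.preload(inputs.precomputed)

    superfamilies = sorted(inputs.family_table["superfamily_id"].unique())
    analyses: list[SuperfamilyAnalysis] = []
    for sf in superfamilies:
        members = {d: inputs.domains[d]
                   for d in inputs.family_table.loc[
                       inputs.family_table["superfamily_id"] == sf, "domain_id"]}
        anns = [a for a in inputs.annotations if a.domain_id in members]
        s60 = _planted_clusters(inputs.family_table, sf)
        analyses.append(analyse_superfamily(sf, members, anns, config=config,
                                            s60=s60, aligner=aligner))
        logger.info("superfamily %s: %s", sf,
                    "excluded: " + analyses[-1].exclusion_reason
                    if analyses[-1].excluded else
                    f"representative {analyses[-1].representative_id}")

    # coverage + colocation + diversity summaries
    cov_rows, col_rows, div_rows = [], [], []
    for a in analyses:
        for st in config.site_types:
            if a.excluded:
                cov_rows.append({"superfamily_id": a.superfamily_id, "site_type": st,
                                 "coverage": "", "n_contributing_domains": 0,
                                 "excluded": True,
                                 "exclusion_reason": a.exclusion_reason})
                continue
            c = a.coverages[st]
            cov_rows.append({"superfamily_id": c.superfamily_id, "site_type": st,
                             "coverage": round(c.coverage, 6),
                             "n_contributing_domains": c.n_contributing_domains,
                             "excluded": c.excluded,
                             "exclusion_reason": c.exclusion_reason})
            r = a.colocations[st]
            col_rows.append({"superfamily_id": r.superfamily_id, "site_type": st,
                             "n_clusters_with_data": r.n_clusters_with_data,
                             "max_fraction": round(r.max_fraction, 6),
                             "included": r.included,
                             "argmax_positions": ",".join(
                                 map(str, sorted(r.argmax_positions)))})
        if not a.excluded:
            for cutoff, cs in a.structural_clusters.items():
                div_rows.append({"superfamily_id": a.superfamily_id,
                                 "cutoff": cutoff, "n_clusters": cs.n_clusters,
                                 "diverse": a.diverse[cutoff]})
    pd.DataFrame(cov_rows).to_csv(out / "coverage_summary.tsv", sep="\t", index=False)
    pd.DataFrame(col_rows).to_csv(out / "colocation_summary.tsv", sep="\t", index=False)
    pd.DataFrame(div_rows).to_csv(out / "diversity_summary.tsv", sep="\t", index=False)

    # exclusion ledger per site type
    led_rows = []
    for st in config.site_types:
        for sf, reason in sorted(exclusion_ledger(analyses, st).items()):
            led_rows.append({"superfamily_id": sf, "site_type": st, "reason": reason})
    pd.DataFrame(led_rows).to_csv(out / "exclusions.tsv", sep="\t", index=False)

    # per-superfamily profiles + B-factor PDBs
    pdir = out / "profiles"
    pdir.mkdir(exist_ok=True)
    for a in analyses:
        if a.excluded or a.profile is None:
            continue
        prof_rows = []
        rep = inputs.domains[a.representative_id]
        for st in config.site_types:
            contribs = a.profile.contributors(st)
            clusters = a.profile.cluster_contributors(st)
            for p in range(a.profile.rep_length):
                if contribs[p]:
                    prof_rows.append({
                        "position": p, "residue": str(rep.refs[p]),
                        "site_type": st, "n_domains": len(contribs[p]),
                        "n_s60_clusters": len(clusters[p]),
                        "domains": ",".join(sorted(contribs[p]))})
        pd.DataFrame(prof_rows, columns=["position", "residue", "site_type",
                                         "n_domains", "n_s60_clusters", "domains"]
                     ).to_csv(pdir / f"{a.superfamily_id}.tsv", sep="\t", index=False)
        for st in config.site_types:
            contribs = a.profile.contributors(st)
            if any(contribs):
                fractions = np.array([len(c) / a.profile.n_domains
                                      for c in contribs])
                write_profile_pdb(rep, fractions,
                                  pdir / f"{a.superfamily_id}_{st}.pdb")

    # hubs
    if inputs.interaction_counts:
        membership = dict(zip(inputs.family_table["domain_id"],
                              inputs.family_table["superfamily_id"]))
        hubs = flag_hub_superfamilies(inputs.interaction_counts, membership,
                                      config.hub_min_interactions)
        pd.DataFrame({"superfamily_id": sorted(superfamilies),
                      "hub": [sf in hubs for sf in sorted(superfamilies)]}
                     ).to_csv(out / "hubs.tsv", sep="\t", index=False)

    # diverse-vs-similar coverage comparison per site type
    cmp_rows = []
    for st in config.site_types:
        covs = {a.superfamily_id: a.coverages[st].coverage for a in analyses
                if not a.excluded and not a.coverages[st].excluded}
        flags = {a.superfamily_id: a.diverse[config.nrmsd_cutoffs[0]]
                 for a in analyses if a.superfamily_id in covs}
        if covs and 0 < sum(flags.values()) < len(flags):
            t = compare_diverse_vs_similar(covs, flags)
            hc = high_coverage_proportion(covs.values())
            cmp_rows.append({"site_type": st, "n": len(covs),
                             "p_value": t.p_value, "method": t.method,
                             "high_coverage_fraction": round(hc.fraction, 6)})
    pd.DataFrame(cmp_rows, columns=["site_type", "n", "p_value", "method",
                                    "high_coverage_fraction"]
                 ).to_csv(out / "coverage_comparison.tsv", sep="\t", index=False)

    # conservation + enrichment over functional-family alignments
    if inputs.family_alignments:
        fam_to_sf = {}
        for row in inputs.family_table.itertuples(index=False):
            if row.funfam_id:
                fam_to_sf[row.funfam_id] = row.superfamily_id
        enr_rows = []
        by_type: dict[str, list[EnrichmentResult]] = {}
        for fam in inputs.family_alignments:
            _, fam_enr = analyse_family_conservation(
                fam, inputs.domains, inputs.annotations, config=config)
            for fe in fam_enr:
                enr_rows.append({"family_id": fe.family_id,
                                 "site_type": fe.site_type,
                                 "pc": fe.enrichment.pc, "pa": fe.enrichment.pa,
                                 "enrichment": fe.enrichment.e,
                                 "defined": fe.enrichment.defined,
                                 "overlap_fraction": fe.overlap_fraction,
                                 "overlap_defined": fe.overlap_defined})
                by_type.setdefault(fe.site_type, []).append(fe.enrichment)
        pd.DataFrame(enr_rows).to_csv(out / "enrichment_per_family.tsv",
                                      sep="\t", index=False)
        test_rows = []
        for st in sorted(by_type):
            sf_level = average_by_superfamily(
                by_type[st], {r.family_id: fam_to_sf.get(r.family_id, r.family_id)
                              for r in by_type[st]})
            if len(sf_level) >= 2:
                t = enrichment_test(sf_level)
                test_rows.append({"site_type": st, "n_superfamilies": len(sf_level),
                                  "mean_enrichment": float(
                                      np.mean([r.e for r in sf_level])),
                                  "p_value": t.p_value, "method": t.method})
        pd.DataFrame(test_rows, columns=["site_type", "n_superfamilies",
                                         "mean_enrichment", "p_value", "method"]
                     ).to_csv(out / "enrichment_tests.tsv", sep="\t", index=False)

    params = {**asdict(config), "nrmsd_cutoffs": list(config.nrmsd_cutoffs),
              "site_types": list(config.site_types)}
    params.pop("input_dir")  # locations are not parameters; digests cover inputs
    params.pop("output_dir")
    manifest = {
        "package": "siteplast",
        "version": __version__,
        "parameters": params,
        "inputs": dict(sorted(inputs.digests.items())),
        "n_superfamilies": len(superfamilies),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
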