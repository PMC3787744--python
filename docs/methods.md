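# Methods

`siteplast` quantifies how diverse the spatial locations of functional
sites are across a superfamily of homologous protein domains.  The core
protocol maps every member's annotated functional residues onto one
structurally chosen representative, and summarises the resulting
per-position profile with four statistics: coverage, preferential
colocation, structural diversity, and conservation-based enrichment.  This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## The mapping protocol

A superfamily is a set of domains, each an ordered CA trace with author
residue numbering.  Domains are grouped into *s60 clusters* (subfamilies at
60% pairwise sequence identity), a widely used proxy for functionally
coherent subgroups.  The analysis:

1. **Representative selection.** Each s60 cluster designates a
   representative (first member by id unless predefined).  All cluster
   representatives are structurally aligned pairwise and the one with the
   highest cumulative similarity score to the others becomes the
   superfamily representative.  Superfamilies with a single s60 cluster are
   excluded — with one subfamily there is no between-subfamily diversity to
   measure.
2. **Site mapping.** Every member with site annotations is aligned against
   the representative; each annotated residue contributes the
   representative position it is paired with.  Residues aligned to gaps are
   dropped.  Per representative position and per site type, the set of
   contributing domains and s60 clusters is recorded.
3. **Coverage** of a site type is the fraction of representative positions
   with at least one contributor.  Two confounders are filtered:
   representatives shorter than 100 residues (small domains trivially
   saturate), and superfamilies where a single domain's own footprint
   exceeds 50% of the representative (coverage then reflects one
   promiscuous member, not cross-family diversity; the comparison is
   strict, so exactly 50% is retained).  A superfamily with no annotation
   of a type scores coverage 0 and is reported, not excluded.
4. **Preferential colocation** is the maximum, over representative
   positions, of the fraction of s60 clusters that have a site at that
   position.  The denominator counts only clusters possessing at least one
   annotation of the same site type — including clusters whose annotated
   residues all fell on alignment gaps (they have data; they simply hit no
   position).  Superfamilies with fewer than 10 such clusters are flagged
   `included=False` so that small denominators cannot produce meaninglessly
   large fractions.
5. **Structural diversity.** Pairwise normalised RMSD
   (RMSD × length of the larger domain / number of aligned pairs) between
   the s60 cluster representatives is thresholded at 9.0 Å (5.0 Å as a
   secondary cutoff) and single-linkage components define structural
   clusters; a superfamily with ≥ 2 clusters is *structurally diverse*.
   Clustering the cluster representatives rather than all members keeps the
   alignment cost linear in subfamilies and reuses the alignments already
   computed for representative selection; diversity is a subfamily-level
   property, so this loses nothing the statistic needs.
6. **Hub flagging.** A superfamily is a hub superfamily if any member's
   parent protein has ≥ 10 physical interaction partners (counts are an
   input, already mapped from proteins to domains).

Site types are `catalytic`, `protein_protein`, `nucleic_acid`, and
`small_ligand` (small organic compounds, peptides and ions pooled), plus
`conserved` for residues called from family alignments.  Annotations for
one domain are unioned over all evidence records, so multiple structures of
the same protein accumulate rather than overwrite.  Surface accessibility
is deliberately not used as a filter: buried residues can be genuinely
functional, and accessibility of a position can differ between structures
of the same protein.

## The pairwise structural aligner

Downstream statistics need residue correspondences, an RMSD and a ranking
score; any sound pairwise structural aligner can supply them (precomputed
alignments drop in through an interchange TSV and give identical results
for identical correspondences).  The built-in aligner is iterative
superposition dynamic programming over CA atoms:

* **Seeding**: global sequence alignment (BLOSUM62, gap open 10 / extend
  0.5) when sequences are available, otherwise the best gapless offset of
  the distance-to-centroid profiles.
* **Iteration**: superpose on the current pairs (Kabsch), score all
  position pairs with s(i,j) = 1/(1 + (d_ij/d0)²), d0 = 3.8 Å (the CA
  virtual bond length), run global Needleman–Wunsch with linear gap
  penalty 0.1 (ties in the traceback resolve toward the diagonal for
  determinism), and repeat until the pair set stabilises or 20 iterations
  pass (best-scoring alignment so far is then returned with a warning
  flag).
* **Trimmed superposition**: within each iteration the transform is
  annealed — the worst-fitting 30% of pairs are dropped and the remainder
  re-fit, repeatedly, until every retained pair is within 7.6 Å (2·d0).
  This anchors the superposition on the rigid conserved core.  Without it,
  conformationally displaced regions drag the compromise fit and can shift
  the core alignment off register, which silently corrupts site mapping
  between conformers.  The reported RMSD is still computed over *all*
  aligned pairs after an unrestricted superposition on them.
* **Score**: 100 × (n_aligned / max(len_a, len_b)) / (1 + (rmsd/d0)²) — 100
  exactly for identical structures fully aligned at RMSD 0, symmetric,
  decreasing in RMSD, increasing in alignment length.  Only its ranking is
  consumed (representative selection), so any score meeting those
  monotonicity contracts would serve.

Self-alignments return the identity pairing at RMSD 0 by construction.
The DP inner loop is JIT-compiled; one 120-residue alignment takes about
2 ms, which is what makes cohort-scale recovery studies practical.

## Conservation scoring and enrichment

Functional-family alignments (FunFams/FineFams are inputs; MAFFT can be
invoked if configured, but pre-built alignments are the normal path) are
scored per column with a Valdar-style weighted sum-of-pairs over ordered
pairs *with replacement*:

    score(c) = Σ_ij w_i w_j M(a_ic, a_jc) / Σ_ij w_i w_j

with M = BLOSUM62 under Karlin normalisation M(a,b)/√(M(a,a)·M(b,b))
clamped to [0,1] (diagonal exactly 1, so an ungapped identity column
scores 1.0), gap-containing pairs scoring 0, and w the Henikoff
position-based sequence weights (gap as a 21st symbol, normalised to
mean 1).  Scoring with replacement makes the column score exactly
invariant under duplicating the entire row set; the self-pair term it adds
vanishes as 1/n.  Min–max normalisation of the raw matrix was rejected
because BLOSUM62's maximum is off-diagonal-specific (W–W), which would
leave identity columns of other residues scoring below 1.

Columns scoring ≥ 0.7 are *conserved*.  The 0.7 threshold is inherited
from practice with Scorecons-family scorers; since this scorer is not
bit-compatible with any particular Scorecons matrix, the threshold should
be read as a calibrated default of this package, not a universal constant.
Fragment removal drops sequences whose ungapped length is below 80% of the
family mean, computed once over all sequences before any removal; with a
single-pass mean the longest sequence always survives, so the procedure
cannot empty a family.

Conserved columns project to per-member `conserved` site annotations
through the alignment (gapped rows contribute nothing), and these flow
through the same mapping machinery as experimental sites.  Enrichment per
family is E = Pc − Pa with Pc the proportion of conserved residues that
are functional and Pa the proportion of all residues that are functional;
families with no conserved residues have Pc undefined and are excluded
from averaging (and reported).  Family-level enrichments are averaged
unweighted within superfamilies before testing, so large superfamilies do
not dominate; the test is a one-sided Wilcoxon rank-sum of Pc against Pa
(a one-sample signed-rank test of E against zero is available as an
option).  P-values are exact by enumeration for tie-free samples of ≤ 25
per group, otherwise a normal approximation with tie and continuity
corrections; no multiple-testing correction is applied by default
(a Bonferroni option exists) since each site type is reported separately.

## The synthetic-data generator

Real inputs at the scale of a full domain-classification release are not
reproducible on a desk, so the package ships a generator whose outputs
carry complete ground truth.  A superfamily derives from one compact
self-avoiding CA template (3.8 ± 0.01 Å bonds, > 2 Å non-bonded clearance,
random sequence).  Defaults: 12 clusters × 2 members, template length 120,
cluster-level coordinate noise 1.0 Å shared by a cluster's members,
per-member noise 0.5 Å, within-cluster sequence identity target 0.90,
between-cluster 0.35 (safely split by the 0.60 clustering threshold), and
one planted `protein_protein` site specification: a 12-residue spatially
compact *preferred* footprint used by a fraction f = 0.8 of clusters, plus
one 6-residue *scattered* site per cluster.  Scattered sites are placed
disjoint from the preferred footprint — that disjointness is what makes
them subfamily-specific, and without it coincidental scatter-on-preferred
hits bias the colocation maximum upward.  Every member is rigidly
re-placed (random rotation + translation); all statistics are
superposition-invariant, so this only exercises the aligner.

Optional features:

* **Embellishments** — surface loops of 8–15 residues inserted at a random
  internal position (shared geometry per superfamily by default), which
  can carry their own planted sites.
* **Structural diversity** — a fraction of clusters receive an alternative
  conformation in which the chain beyond 60% of the template is regrown as
  an independent, outward-growing self-avoiding walk.  A refolded tail is
  incoherent with the original, so no rigid superposition absorbs the
  displacement; candidates are resampled until the whole-domain
  superposed RMSD between conformers is ≥ 16 Å.  The margin over the 9 Å
  clustering cutoff is deliberately large because an aligner may re-pair
  tail residues off the diagonal and trade pairs for gaps, both of which
  shrink the measured normalised RMSD relative to the fixed-correspondence
  RMSD.  (An earlier rigid-hinge design was abandoned: optimal
  superposition splits a rigid two-body displacement and routinely pulled
  the measured separation below the cutoff.)
* **Core-only site placement** — restricts planted sites to the region
  well before the refold pivot.  The diversity cohort studies use it so
  that, in matched null cohorts, site mapping is equally reliable in both
  conformational groups and the two groups' coverages are exchangeable.
* **Pseudo-ligand sites** — residues within 4.0 Å of a synthetic ligand
  point cloud, mirroring the distance rule interaction databases use to
  call binding residues.
* **Interaction counts** — Poisson(3) per domain, for hub flagging.

Sequence-only *conservation families* are generated separately: 12 rows ×
120 columns, 10 planted functional columns that are near-identical across
rows (mutation probability 0.05) when the signal is on, background columns
sharing a consensus residue with probability 0.5, and optionally 50% of
rows truncated to a contiguous 50%-length window (fragments).  In the null
configuration the functional columns behave like background, so conserved
calls and functional residues are unrelated.

All randomness descends from a single seed via `numpy.random.SeedSequence`
spawning, so any subset of superfamilies regenerates identically.

## What the benchmarks show — and what they do not

The recovery studies (see `scripts/acceptance.py`) demonstrate, on these
synthetic conditions: exact agreement of coverage, colocation, structural
clustering and exact rank-sum p-values with brute-force oracles; recovery
of the planted preferred-usage fraction f within ±0.1 (the residual bias
is the ±0.033 quantisation of round(f × 12) clusters); coverage within
±0.1 of the planted union footprint; one-sided detection of higher
coverage in structurally diverse superfamilies carrying embellishment-borne
sites, with matched-null type-I rates near 0.05; positive enrichment with
near-certain rejection when conserved columns coincide with functional
residues, null rejection near 0.05; and a consistent rise in recovered
functional columns after fragment removal.

Synthetic members are noisy copies of one template: they do not model
real indel variation beyond single embellishment loops, domain repeats,
genuinely gradual structural drift, alignment ambiguity in twilight-zone
homologues, or the strong ascertainment biases of experimental site data.
Passing these benchmarks therefore shows the machinery is correct and
well-calibrated under controlled conditions; it does not certify accuracy
on any particular real superfamily, where alignment quality and data
sparsity dominate.

## Numerical and engineering choices

* Positions are 0-based dense indices internally; every file-facing
  residue identity is author numbering (chain, number, insertion code).
  Only CA atoms are used; first model of multi-model files; altloc
  resolved to highest occupancy, ties to file order.
* Sequence identity = identical aligned positions / shorter sequence
  length, global Needleman–Wunsch under BLOSUM62 (gap 10/0.5) — the
  convention of greedy incremental clustering tools; s60 clustering is
  greedy longest-first with deterministic (length desc, id asc) ordering.
* Single linkage for structural clusters — the unique linkage expressible
  as "connected at a cutoff", verifiable against a graph-components
  oracle.
* Representative ties break to the lexicographically smallest domain id.
* Heat-map colour bins: 0 exactly grey, then half-open 20% bands
  (boundary values assigned upward), 100% red.
* Cohort studies use deliberately small superfamilies (3 clusters × 1
  member, 110-residue templates) and the recovery studies 12 × 2 at length
  120 — sizes chosen so a full multi-cohort calibration runs in minutes on
  one core while leaving every filter (length ≥ 100, dominance, minimum
  clusters) on its operative branch.
* The pipeline is deterministic for fixed inputs and configuration; rerun
  summary tables are byte-identical, and the run manifest records
  parameters and input digests (not paths).

## Known limitations

* The aligner is CA-only and sequence-seeded; on real remote homologues
  (< 20% identity) the seed can be poor and convergence to the best core
  is not guaranteed — the interchange format exists precisely so that a
  production structural aligner can be substituted.
* The conservation scorer approximates, but does not reproduce, any
  specific published Scorecons matrix; absolute threshold transferability
  is limited (see above).
* The colocation maximum is an extreme-value statistic and inherits an
  upward bias of order one cluster when background sites can coincide with
  the preferred footprint.
* Normalised RMSD depends on the aligner's gap behaviour; comparing values
  across aligners requires consistent correspondence conventions.
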