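# siteplast

Quantitative analysis of **functional-site plasticity** in protein domain
superfamilies: do homologous domains use the same spatial locations for
catalysis and binding, or does each subfamily exploit its own patch of the
domain surface?

`siteplast` is aimed at structural bioinformaticians who have, for each
domain superfamily, a set of member structures (CA traces suffice), a table
of subfamily membership, and per-domain functional-site annotations
(catalytic residues, protein–protein interface residues, nucleic-acid and
small-ligand binding residues).  It answers, per superfamily and site type:

* **Coverage** — what fraction of a structurally chosen representative is
  touched by at least one member's sites?  High coverage in a large, diverse
  superfamily means relatives have spread their functional sites over most
  of the domain.
* **Preferential colocation** — is there a position used by a majority of
  sequence subfamilies (s60 clusters)?  Reported as the maximum fraction of
  clusters sharing a site at one position.
* **Structural diversity** — does the superfamily split into ≥ 2 clusters
  at a 9.0 Å normalised-RMSD cutoff, and do structurally diverse
  superfamilies have higher site coverage?
* **Conservation & enrichment** — are conserved residues of functional
  families (called at a 0.7 conservation score) enriched in known
  functional residues (E = Pc − Pa, Wilcoxon rank-sum on Pc vs Pa)?

## The core protocol

For each superfamily with ≥ 2 s60 clusters, the member with the highest
cumulative structural-similarity score to the other cluster representatives
becomes the superfamily representative.  Every member is structurally
aligned to it (iterative Kabsch-superposition dynamic programming over CA
atoms; precomputed alignments from external aligners are accepted), and
each annotated residue is projected through the alignment onto a
representative position (gap-aligned residues are dropped).  Then

```
coverage      = |{positions with ≥ 1 contributor}| / rep_length
max_fraction  = max over positions of  |clusters with a site there| /
                                       |clusters with site data|
nRMSD(a, b)   = RMSD × max(len_a, len_b) / n_aligned_pairs
E             = Pc − Pa
```

with the published filters: representatives ≥ 100 residues, exclusion when
one domain alone covers > 50% of the representative, colocation restricted
to superfamilies with ≥ 10 clusters with data, sequence fragments < 80% of
the family mean length removable before conservation scoring.

Because full structure/annotation database snapshots are not reproducible
at desk scale, the package includes a first-class synthetic-data generator:
seeded superfamilies of perturbed template copies with planted preferred
sites (used by a controlled fraction *f* of clusters), cluster-specific
scattered sites, embellishment loops, refolded-tail conformational groups,
and full ground truth for every downstream statistic.

## Worked example

Generate two synthetic superfamilies (12 s60 clusters × 2 members each,
preferred-site usage f = 0.8) and run the full pipeline:

```python
from siteplast import RunConfig
from siteplast.pipeline import run_all, write_synthetic_inputs
from siteplast.synthetic_data import SyntheticConfig, PlantedSiteSpec, make_cohort

cohort = make_cohort(SyntheticConfig(
    n_superfamilies=2, clusters_per_superfamily=12, members_per_cluster=2,
    planted_sites=(PlantedSiteSpec(preferred_fraction=0.8),)), seed=17)
write_synthetic_inputs(cohort, "demo/inputs")
run_all(RunConfig(input_dir="demo/inputs", output_dir="demo/run",
                  site_types=("protein_protein",)))
```

`demo/run/coverage_summary.tsv`:

```
superfamily_id  site_type        coverage  n_contributing_domains  excluded  exclusion_reason
SF0000          protein_protein  0.541667  24                      False     none
SF0001          protein_protein  0.65      24                      False     none
```

`demo/run/colocation_summary.tsv`:

```
superfamily_id  site_type        n_clusters_with_data  max_fraction  included  argmax_positions
SF0000          protein_protein  12                    0.833333      True      79,80,106,...
SF0001          protein_protein  12                    0.833333      True      6,7,46,...
```

Reading: in SF0000, 54.2% of representative positions carry a
protein–protein interface residue in at least one of the 24 members — the
generator's ground-truth union footprint is 54.17%, so mapping recovered it
exactly.  The colocation maximum 0.833 = 10/12 clusters sharing one
position recovers the planted usage fraction f = 0.8 (10 of 12 clusters
were planted users; `round(0.8 × 12) = 10`).  Both superfamilies pass the
length and dominance filters (`excluded False`).

The same stages are available from a CLI:

```bash
siteplast simulate --seed 17 --out demo/inputs --n-superfamilies 2
siteplast run-all --input-dir demo/inputs --out demo/run
siteplast report --run-dir demo/run
```

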