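"""Readers and writers for the formats the pipeline exchanges on disk.

Residue identity in every file-facing format follows the PDB author
convention: a one-character chain id, an integer residue number, and an
optional insertion code.  Internally each domain uses a dense 0-based
positional index in file order; :class:`DomainStructure` owns the mapping
between the two.

Only CA atoms are read (the whole analysis operates on CA traces); for
multi-model files the first model is used, and alternate locations are
resolved to the highest-occupancy conformer (ties: first in file order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

logger = logging.getLogger(__name__)

#: Recognised functional-site categories.  ``small_ligand`` pools small
#: organic compounds, peptides and ions; ``conserved`` holds residues called
#: conserved from functional-family alignments and is treated like any other
#: site type downstream.
SITE_TYPES = ("catalytic", "protein_protein", "nucleic_acid", "small_ligand", "conserved")


class ResidueRef(NamedTuple):
    """Author-numbering identity of one residue: (chain, number, icode)."""

    chain: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:42" or "A:42A"
        return f"{self.chain}:{self.number}{self.icode}"


def parse_residue_ref(text: str) -> ResidueRef:
    """Parse ``"A:42"`` / ``"A:42B"`` back into a :class:`ResidueRef`."""
    chain, _, rest = text.partition(":")
    num = ""
    i = 0
    if rest[:1] == "-":
        num = "-"
        i = 1
    while i < len(rest) and rest[i].isdigit():
        num += rest[i]
        i += 1
    return ResidueRef(chain, int(num), rest[i:])


@dataclass
class DomainStructure:
    """One protein domain as an ordered CA trace.

    ``refs``, ``sequence`` and ``coords`` run in file order and share the
    same dense 0-based index.
    """

    domain_id: str
    refs: list[ResidueRef]
    sequence: str
    coords: np.ndarray  # shape (n, 3), Angstroms
    superfamily_id: str = ""
    s60_cluster_id: str | None = None
    _index: dict[ResidueRef, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.refs)
        if n < 1:
            raise ValueError(f"domain {self.domain_id}: must contain at least one residue")
        if len(self.sequence) != n or self.coords.shape != (n, 3):
            raise ValueError(
                f"domain {self.domain_id}: refs/sequence/coords lengths disagree "
                f"({n}/{len(self.sequence)}/{self.coords.shape})"
            )
        self._index = {}
        for i, ref in enumerate(self.refs):
            if ref in self._index:
                raise ValueError(f"domain {self.domain_id}: duplicate residue {ref}")
            self._index[ref] = i

    @property
    def length(self) -> int:
        return len(self.refs)

    @property
    def residues(self) -> Iterator[tuple[ResidueRef, str, np.ndarray]]:
        for i, ref in enumerate(self.refs):
            yield ref, self.sequence[i], self.coords[i]

    def index_of(self, ref: ResidueRef) -> int:
        """0-based position of an author-numbered residue (KeyError if absent)."""
        return self._index[ref]

    def __contains__(self, ref: ResidueRef) -> bool:
        return ref in self._index


@dataclass
class SiteAnnotation:
    """Typed functional residues of one domain, unioned over evidence records."""

    domain_id: str
    site_type: str
    residues: set[ResidueRef]
    evidence_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(
                f"unknown site_type {self.site_type!r}; expected one of {SITE_TYPES}"
            )
        self.residues = set(self.residues)
        self.evidence_ids = set(self.evidence_ids)


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_domain_pdb(path: str | Path, domain_id: str | None = None,
                    superfamily_id: str = "") -> DomainStructure:
    """Read one domain (CA trace) from a PDB file.

    First model only; per residue the highest-occupancy CA is kept
    (ties broken by file order); everything that is not a CA atom is ignored.
    """
    path = Path(path)
    if domain_id is None:
        domain_id = path.stem
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no CA atoms")
    model = st[0]
    refs: list[ResidueRef] = []
    seq: list[str] = []
    coords: list[list[float]] = []
    seen: set[ResidueRef] = set()
    for chain in model:
        for res in chain:
            cas = [a for a in res if a.name == "CA" and a.element != gemmi.Element("Ca")]
            if not cas:
                continue
            best = max(cas, key=lambda a: a.occ)  # max() keeps the first on ties
            ref = ResidueRef(chain.name, res.seqid.num, res.seqid.icode.strip())
            if ref in seen:
                raise ValueError(f"{path}: duplicate residue {ref}")
            seen.add(ref)
            info = gemmi.find_tabulated_residue(res.name)
            one = info.one_letter_code.upper() if info else "X"
            seq.append(one if one.isalpha() else "X")
            refs.append(ref)
            coords.append([best.pos.x, best.pos.y, best.pos.z])
    if not refs:
        raise ValueError(f"{path}: no CA atoms")
    return DomainStructure(domain_id, refs, "".join(seq), np.array(coords),
                           superfamily_id=superfamily_id)


def write_domain_pdb(domain: DomainStructure, path: str | Path,
                     bfactors: Sequence[float] | None = None) -> None:
    """Write a domain's CA trace as a PDB file (optionally with B-factors)."""
    if bfactors is not None and len(bfactors) != domain.length:
        raise ValueError(
            f"domain {domain.domain_id}: {len(bfactors)} B-factors for "
            f"{domain.length} residues"
        )
    st = gemmi.Structure()
    st.name = domain.domain_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for i, (ref, aa, xyz) in enumerate(domain.residues):
        if ref.chain not in chains:
            chains[ref.chain] = gemmi.Chain(ref.chain)
        res = gemmi.Residue()
        res.name = seq3(aa).upper() if aa != "X" else "UNK"
        res.seqid = gemmi.SeqId(ref.number, ref.icode or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = float(bfactors[i]) if bfactors is not None else 0.0
        res.add_atom(atom)
        chains[ref.chain].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_profile_pdb(rep_domain: DomainStructure,
                      per_position_fraction: Sequence[float],
                      path: str | Path) -> None:
    """Write the representative with per-position fractions in the B-factor
    column (fraction x 100, 2 decimals) plus a companion TSV of exact values.
    """
    fractions = np.asarray(per_position_fraction, dtype=float)
    if fractions.shape != (rep_domain.length,):
        raise ValueError(
            f"expected {rep_domain.length} fractions, got {fractions.shape}"
        )
    bf = np.round(fractions * 100.0, 2)
    write_domain_pdb(rep_domain, path, bfactors=bf)
    rows = [
        {"position": i, "chain": ref.chain, "resnum": ref.number,
         "icode": ref.icode, "fraction": fractions[i]}
        for i, ref in enumerate(rep_domain.refs)
    ]
    pd.DataFrame(rows).to_csv(str(path) + ".tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences keyed by record id (order-preserving dict)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Site annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationLoadReport:
    """Bookkeeping from :func:`read_site_annotations`."""

    n_rows: int = 0
    n_rejected: int = 0
    n_dropped_not_relevant: int = 0
    rejected: list[str] = field(default_factory=list)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def read_site_annotations(path: str | Path,
                          domains: Mapping[str, DomainStructure],
                          ) -> tuple[list[SiteAnnotation], AnnotationLoadReport]:
    """Load a site-annotation TSV and merge rows into per-(domain, type) unions.

    Expected columns: domain_id, site_type, chain, resnum, icode, evidence_id;
    an optional boolean ``biologically_relevant`` column drops rows that are
    false (the upstream curation contract).  Rows naming residues or domains
    that cannot be resolved are rejected, counted and reported, never fatal;
    an unknown site_type is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"domain_id", "site_type", "chain", "resnum", "icode", "evidence_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    report = AnnotationLoadReport(n_rows=len(df))
    merged: dict[tuple[str, str], SiteAnnotation] = {}
    for row in df.itertuples(index=False):
        if row.site_type not in SITE_TYPES:
            raise ValueError(f"{path}: unknown site_type {row.site_type!r}")
        if "biologically_relevant" in df.columns:
            flag = str(getattr(row, "biologically_relevant")).strip().lower()
            if flag in _FALSE:
                report.n_dropped_not_relevant += 1
                continue
        ref = ResidueRef(row.chain, int(row.resnum), row.icode.strip())
        dom = domains.get(row.domain_id)
        if dom is None or ref not in dom:
            report.n_rejected += 1
            report.rejected.append(f"{row.domain_id}\t{row.site_type}\t{ref}")
            continue
        key = (row.domain_id, row.site_type)
        if key not in merged:
            merged[key] = SiteAnnotation(row.domain_id, row.site_type, set(), set())
        merged[key].residues.add(ref)
        merged[key].evidence_ids.add(row.evidence_id)
    if report.n_rejected:
        logger.info("%s: rejected %d unresolvable site rows", path, report.n_rejected)
    return list(merged.values()), report


def write_site_annotations(annotations: Iterable[SiteAnnotation],
                           path: str | Path) -> None:
    """Write annotations in the same TSV layout read_site_annotations expects.

    The per-residue evidence association is not retained in memory, so every
    evidence id of an annotation is written against each of its residues
    (union semantics make the round trip exact).
    """
    rows = []
    for ann in annotations:
        for ref in sorted(ann.residues):
            for ev in sorted(ann.evidence_ids) or [""]:
                rows.append({"domain_id": ann.domain_id, "site_type": ann.site_type,
                             "chain": ref.chain, "resnum": ref.number,
                             "icode": ref.icode, "evidence_id": ev})
    pd.DataFrame(rows, columns=["domain_id", "site_type", "chain", "resnum",
                                "icode", "evidence_id"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Family membership tables
# ---------------------------------------------------------------------------

FAMILY_COLUMNS = ["domain_id", "superfamily_id", "s60_cluster_id", "funfam_id"]


def read_family_table(path: str | Path) -> pd.DataFrame:
    """Family membership TSV: domain_id, superfamily_id, s60_cluster_id, funfam_id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "domain_id" not in df.columns or "superfamily_id" not in df.columns:
        raise ValueError(f"{path}: family table needs domain_id and superfamily_id")
    for col in FAMILY_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df[FAMILY_COLUMNS]


def write_family_table(df: pd.DataFrame, path: str | Path) -> None:
    df.reindex(columns=FAMILY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_interaction_counts(path: str | Path) -> dict[str, int]:
    """TSV with columns domain_id, n_interactions."""
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str, "n_interactions": int})
    return dict(zip(df["domain_id"], df["n_interactions"]))


def write_interaction_counts(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"domain_id": list(counts), "n_interactions": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignment interchange TSV
# ---------------------------------------------------------------------------

def write_alignment_tsv(alignment, domain_a: DomainStructure,
                        domain_b: DomainStructure, path: str | Path) -> None:
    """Serialise a StructuralAlignment as the interchange TSV.

    Header lines carry #score, #rmsd and #n_aligned; data rows list the
    paired residues in author numbering for both domains.
    """
    if (alignment.domain_a, alignment.domain_b) != (domain_a.domain_id, domain_b.domain_id):
        raise ValueError("alignment ids do not match the supplied domains")
    with open(path, "w") as fh:
        fh.write(f"#score\t{alignment.score:.6g}\n")
        fh.write(f"#rmsd\t{alignment.rmsd:.6g}\n")
        fh.write(f"#n_aligned\t{alignment.n_aligned}\n")
        fh.write("domain_a\tchain_a\tresnum_a\ticode_a\t"
                 "domain_b\tchain_b\tresnum_b\ticode_b\n")
        for i, j in alignment.pairs:
            ra, rb = domain_a.refs[i], domain_b.refs[j]
            fh.write(f"{domain_a.domain_id}\t{ra.chain}\t{ra.number}\t{ra.icode}\t"
                     f"{domain_b.domain_id}\t{rb.chain}\t{rb.number}\t{rb.icode}\n")


def read_alignment_tsv(path: str | Path,
                       domains: Mapping[str, DomainStructure]):
    """Read an interchange TSV back into a StructuralAlignment.

    Positions are resolved through the supplied domains so precomputed
    alignments (e.g. converted SSAP/TM-align output) drop straight into the
    pipeline.
    """
    from .pairwise_align import StructuralAlignment  # local import: avoid cycle

    header: dict[str, str] = {}
    pairs: list[tuple[int, int]] = []
    id_a = id_b = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("\t")
                header[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "domain_a":  # column header row
                continue
            da, ca, na, ia, db, cb, nb, ib = (parts + [""] * 8)[:8]
            id_a, id_b = da, db
            dom_a, dom_b = domains[da], domains[db]
            pairs.append((dom_a.index_of(ResidueRef(ca, int(na), ia.strip())),
                          dom_b.index_of(ResidueRef(cb, int(nb), ib.strip()))))
    if not pairs or id_a is None:
        raise ValueError(f"{path}: no aligned residue pairs")
    return StructuralAlignment(
        domain_a=id_a, domain_b=id_b, pairs=pairs,
        rmsd=float(header.get("rmsd", "nan")),
        score=float(header.get("score", "nan")),
    )
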