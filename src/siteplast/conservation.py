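"""Conservation scoring of functional-family alignments.

Columns are scored with a Valdar-style weighted sum-of-pairs taken over
ordered pairs with replacement:

    score(c) = sum_{i,j} w_i w_j M(a_ic, a_jc) / sum_{i,j} w_i w_j

where M is BLOSUM62 normalised so that every identity pair scores exactly 1
(Karlin normalisation M(a,b)/sqrt(M(a,a) M(b,b)), negatives clamped to 0)
and any pair involving a gap scores 0 (including the gap self-pair).  The
w_i are Henikoff position-based sequence weights (gaps treated as a 21st
symbol) normalised to mean 1.  Scoring with replacement rather than over
distinct pairs makes the score exactly invariant under appending a
duplicate of the whole row set; the self-pair term it adds vanishes as
1/n.  A column of identical residues with no gaps scores 1.0 and an
all-gap column scores 0.

Residues in columns scoring at or above a threshold (0.7 by default) are
called conserved; projected back onto each member's structure they form a
"conserved" site annotation that runs through the same mapping machinery as
experimentally known sites.  Families are optionally stripped of sequence
fragments (ungapped length below 80% of the family mean) before scoring,
which removes gap-riddled columns' penalty and raises scores at genuinely
conserved positions.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .structure_io import (
    DomainStructure,
    SiteAnnotation,
    read_fasta,
    write_fasta,
)

GAP = "-"
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_GAP_INDEX = len(_ALPHABET)  # gaps and unknown residues share the null symbol


@dataclass
class FamilyAlignment:
    """A multiple sequence alignment of one functional family."""

    family_id: str
    ids: list[str]
    rows: list[str]
    family_kind: str = "funfam"  # or "finefam"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("alignment has no rows")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError(f"family {self.family_id}: rows differ in length")
        if self.family_kind not in ("funfam", "finefam"):
            raise ValueError(f"unknown family kind {self.family_kind!r}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path, family_id: str | None = None,
                   family_kind: str = "funfam") -> "FamilyAlignment":
        seqs = read_fasta(path)
        return cls(family_id or Path(path).stem, list(seqs), list(seqs.values()),
                   family_kind=family_kind)

    def to_fasta(self, path) -> None:
        write_fasta(dict(zip(self.ids, self.rows)), path)

    def subset(self, keep_ids: Iterable[str]) -> "FamilyAlignment":
        keep = set(keep_ids)
        ids, rows = [], []
        for i, r in zip(self.ids, self.rows):
            if i in keep:
                ids.append(i)
                rows.append(r)
        return FamilyAlignment(self.family_id, ids, rows, self.family_kind)


@dataclass
class ConservationProfile:
    scores: np.ndarray
    threshold: float = 0.7
    conserved_columns: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        expected = {int(i) for i in np.nonzero(self.scores >= self.threshold)[0]}
        if not self.conserved_columns:
            self.conserved_columns = expected
        elif self.conserved_columns != expected:
            raise ValueError("conserved_columns inconsistent with scores/threshold")


# ---------------------------------------------------------------------------
# Fragment removal
# ---------------------------------------------------------------------------

def remove_fragments(sequences: Mapping[str, str],
                     fraction: float = 0.8) -> dict[str, str]:
    """Drop sequences shorter than ``fraction`` of the family mean length.

    Lengths are counted on ungapped sequences; the mean is computed once
    over ALL input sequences before any removal (single pass).  A sequence
    of length exactly fraction x mean is retained (only strictly shorter
    ones are fragments).
    """
    if not sequences:
        raise ValueError("no sequences given")
    lengths = {k: len(s.replace(GAP, "")) for k, s in sequences.items()}
    cutoff = fraction * float(np.mean(list(lengths.values())))
    kept = {k: s for k, s in sequences.items() if lengths[k] >= cutoff}
    if not kept:
        raise ValueError("fragment removal discarded every sequence")
    return kept


def remove_fragment_rows(alignment: FamilyAlignment,
                         fraction: float = 0.8) -> FamilyAlignment:
    """Fragment removal applied to alignment rows (columns untouched)."""
    kept = remove_fragments(dict(zip(alignment.ids, alignment.rows)), fraction)
    return alignment.subset(kept)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _pair_matrix() -> np.ndarray:
    """21x21 pair-score matrix: Karlin-normalised BLOSUM62 with a null row."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(_ALPHABET)
    m = np.zeros((n + 1, n + 1))
    diag = np.array([blosum[a, a] for a in _ALPHABET])
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            m[i, j] = blosum[a, b] / np.sqrt(diag[i] * diag[j])
    np.clip(m, 0.0, 1.0, out=m)
    return m


def _encode(rows: list[str]) -> np.ndarray:
    lut = np.full(128, _GAP_INDEX, dtype=np.int64)
    for i, a in enumerate(_ALPHABET):
        lut[ord(a)] = i
        lut[ord(a.lower())] = i
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(rows), -1)


def henikoff_weights(alignment: FamilyAlignment) -> np.ndarray:
    """Position-based sequence weights, normalised to mean 1.

    w_i = mean over columns of 1 / (k_c * n_{a_ic, c}) with k_c the number
    of distinct symbols in column c and n the count of sequence i's symbol
    there; gaps count as their own symbol.
    """
    enc = _encode(alignment.rows)
    n_rows, n_cols = enc.shape
    w = np.zeros(n_rows)
    for c in range(n_cols):
        col = enc[:, c]
        symbols, inverse, counts = np.unique(col, return_inverse=True,
                                             return_counts=True)
        w += 1.0 / (len(symbols) * counts[inverse])
    w /= n_cols
    return w / w.mean()


def conservation_scores(alignment: FamilyAlignment,
                        threshold: float = 0.7,
                        weights: np.ndarray | None = None) -> ConservationProfile:
    """Weighted sum-of-pairs conservation score per column, in [0, 1]."""
    if alignment.n_rows < 2:
        raise ValueError("conservation scoring needs at least 2 rows")
    enc = _encode(alignment.rows)
    if weights is None:
        weights = henikoff_weights(alignment)
    w = np.asarray(weights, dtype=float)
    pair = _pair_matrix()
    wij = np.outer(w, w)
    denom = wij.sum()
    n_cols = enc.shape[1]
    scores = np.empty(n_cols)
    for c in range(n_cols):
        col = enc[:, c]
        v = pair[col[:, None], col[None, :]]
        scores[c] = np.sum(wij * v) / denom
    return ConservationProfile(scores=scores, threshold=threshold)


# ---------------------------------------------------------------------------
# Projection to structures
# ---------------------------------------------------------------------------

def conserved_to_sites(profile: ConservationProfile,
                       alignment: FamilyAlignment,
                       domains: Mapping[str, DomainStructure],
                       ) -> list[SiteAnnotation]:
    """Turn conserved columns into per-member 'conserved' site annotations.

    For each member, residues sitting (ungapped) in conserved columns are
    annotated, expressed in the member's own author numbering.  Rows without
    a matching structure, or whose ungapped length disagrees with the
    structure, are skipped with a warning.
    """
    out: list[SiteAnnotation] = []
    for seq_id, row in zip(alignment.ids, alignment.rows):
        dom = domains.get(seq_id)
        if dom is None:
            warnings.warn(f"alignment row {seq_id} has no structure; skipped",
                          stacklevel=2)
            continue
        ungapped = sum(1 for ch in row if ch != GAP)
        if ungapped != dom.length:
            warnings.warn(
                f"row {seq_id}: ungapped length {ungapped} != structure "
                f"length {dom.length}; skipped", stacklevel=2)
            continue
        residues = set()
        pos = 0
        for col, ch in enumerate(row):
            if ch == GAP:
                continue
            if col in profile.conserved_columns:
                residues.add(dom.refs[pos])
            pos += 1
        if residues:
            out.append(SiteAnnotation(seq_id, "conserved", residues,
                                      {alignment.family_id}))
    return out


@dataclass
class OverlapResult:
    """Proportion of functional residues recovered by conserved residues."""

    n_overlap: int
    n_functional: int
    defined: bool

    @property
    def fraction(self) -> float:
        return self.n_overlap / self.n_functional if self.defined else 0.0


def overlap_proportion(conserved_sites: Iterable[SiteAnnotation],
                       functional_sites: Iterable[SiteAnnotation],
                       site_type: str) -> OverlapResult:
    """|functional & conserved| / |functional| over all family members.

    Undefined (flagged, fraction reported as 0) when the family has no
    functional residues of the requested type.
    """
    conserved: dict[str, set] = {}
    for ann in conserved_sites:
        if ann.site_type == "conserved":
            conserved.setdefault(ann.domain_id, set()).update(ann.residues)
    n_func = 0
    n_overlap = 0
    for ann in functional_sites:
        if ann.site_type != site_type:
            continue
        n_func += len(ann.residues)
        n_overlap += len(ann.residues & conserved.get(ann.domain_id, set()))
    return OverlapResult(n_overlap, n_func, defined=n_func > 0)


# ---------------------------------------------------------------------------
# Optional external MSA construction
# ---------------------------------------------------------------------------

def align_with_mafft(sequences: Mapping[str, str], family_id: str,
                     family_kind: str = "funfam",
                     mafft_path: str | None = None) -> FamilyAlignment:
    """Build a family alignment with an external MAFFT binary, if available.

    MSA construction is pluggable: pre-built alignments can always be read
    with :meth:`FamilyAlignment.from_fasta` instead, so no external binary
    is required anywhere else in the package.
    """
    exe = mafft_path or shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft binary not found; supply a pre-built alignment")
    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "in.fasta"
        write_fasta(sequences, inp)
        res = subprocess.run([exe, "--auto", "--quiet", str(inp)],
                             capture_output=True, text=True, check=True)
        out = Path(tmp) / "out.fasta"
        out.write_text(res.stdout)
        aligned = read_fasta(out)
    return FamilyAlignment(family_id, list(aligned), list(aligned.values()),
                           family_kind=family_kind)
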