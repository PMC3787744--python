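"""Fragment removal, sum-of-pairs conservation scoring, and the projection
of conserved columns onto member structures."""

import itertools

import numpy as np
import pytest

from siteplast import (
    conservation_scores,
    conserved_to_sites,
    overlap_proportion,
    remove_fragments,
)
from siteplast.conservation import (
    FamilyAlignment,
    _encode,
    _pair_matrix,
    henikoff_weights,
    remove_fragment_rows,
)
from siteplast.structure_io import ResidueRef, SiteAnnotation
from siteplast.synthetic_data import make_conservation_family, make_template

from conftest import make_domain


class TestRemoveFragments:
    def test_short_sequence_removed(self):
        seqs = {"a": "A" * 100, "b": "A" * 95, "c": "A" * 60}
        kept = remove_fragments(seqs)  # mean 85, cutoff 68
        assert set(kept) == {"a", "b"}

    def test_equal_lengths_nothing_removed(self):
        seqs = {f"s{i}": "A" * 50 for i in range(4)}
        assert set(remove_fragments(seqs)) == set(seqs)

    def test_exactly_eighty_percent_retained(self):
        # lengths 100,100,100,100,80: mean 96, cutoff 76.8 -> 80 kept;
        # construct an exact-boundary case: lengths 100,100,60 -> mean 86.67
        seqs = {"a": "A" * 110, "b": "A" * 90, "c": "A" * 80}  # mean 100 ssss
        kept = remove_fragments(seqs)  # cutoff exactly 80 -> c retained
        assert "c" in kept

    def test_gaps_not_counted(self):
        seqs = {"a": "AAAA----", "b": "AAAAAAAA"}  # lengths 4 and 8, mean 6
        kept = remove_fragments(seqs)  # cutoff 4.8 -> a removed
        assert set(kept) == {"b"}

    def test_empty_input_is_error(self):
        # with a single-pass mean the longest sequence always survives, so
        # the only degenerate case left is an empty family
        with pytest.raises(ValueError, match="no sequences"):
            remove_fragments({})


class TestConservationScores:
    def test_identity_column_scores_one(self):
        fam = FamilyAlignment("f", ["a", "b", "c", "d"], ["A", "A", "A", "A"])
        assert conservation_scores(fam).scores[0] == pytest.approx(1.0)

    def test_gap_lowers_score(self):
        full = FamilyAlignment("f", list("abcd"), ["A", "A", "A", "A"])
        gapped = FamilyAlignment("f", list("abcd"), ["A", "-", "A", "A"])
        assert conservation_scores(gapped).scores[0] < \
            conservation_scores(full).scores[0]

    def test_all_gap_column_scores_zero(self):
        fam = FamilyAlignment("f", list("ab"), ["-A", "-A"])
        assert conservation_scores(fam).scores[0] == 0.0

    def test_uniform_column_scores_low(self, rng):
        residues = [list("ACDEFGHIKLMNPQRSTVWY")[i % 20] for i in range(50)]
        fam = FamilyAlignment("f", [f"s{i}" for i in range(50)],
                              [r for r in residues])
        assert conservation_scores(fam).scores[0] < 0.2

    def test_matches_sum_of_pairs_bruteforce(self, rng):
        """Vectorised scorer equals a literal loop over ordered residue pairs."""
        aa = "ACDEFGHIKLMNPQRSTVWY-"
        rows = ["".join(rng.choice(list(aa), size=8)) for _ in range(6)]
        fam = FamilyAlignment("f", [f"s{i}" for i in range(6)], rows)
        w = henikoff_weights(fam)
        pair = _pair_matrix()
        enc = _encode(rows)
        prof = conservation_scores(fam)
        for c in range(8):
            num = sum(w[i] * w[j] * pair[enc[i, c], enc[j, c]]
                      for i, j in itertools.product(range(6), repeat=2))
            den = sum(w[i] * w[j]
                      for i, j in itertools.product(range(6), repeat=2))
            assert prof.scores[c] == pytest.approx(num / den)

    def test_invariant_under_row_permutation(self, rng):
        aln, _ = make_conservation_family(3, n_sequences=8, length=30)
        perm = rng.permutation(8)
        shuffled = FamilyAlignment(aln.family_id,
                                   [aln.ids[i] for i in perm],
                                   [aln.rows[i] for i in perm])
        np.testing.assert_allclose(conservation_scores(aln).scores,
                                   conservation_scores(shuffled).scores)

    def test_invariant_under_duplicating_row_set(self):
        """Henikoff weighting makes an exact duplicate of the whole row set
        a no-op."""
        aln, _ = make_conservation_family(4, n_sequences=6, length=25)
        doubled = FamilyAlignment(aln.family_id,
                                  aln.ids + [i + "_dup" for i in aln.ids],
                                  aln.rows + aln.rows)
        np.testing.assert_allclose(conservation_scores(aln).scores,
                                   conservation_scores(doubled).scores,
                                   atol=1e-9)

    def test_conserved_columns_shrink_as_threshold_rises(self):
        aln, _ = make_conservation_family(5, n_sequences=10, length=60)
        sizes = [len(conservation_scores(aln, threshold=t).conserved_columns)
                 for t in (0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_fragment_removal_raises_scores(self):
        """Dropping planted 50%-length fragments raises conservation scores
        on most columns (trend over 20 seeded replicates)."""
        wins = 0
        for seed in range(20):
            aln, _ = make_conservation_family(seed, fragment_fraction=0.5)
            pre = conservation_scores(aln).scores
            post = conservation_scores(remove_fragment_rows(aln)).scores
            if np.mean(post >= pre) >= 0.8:
                wins += 1
        assert wins >= 16


class TestConservedToSites:
    def test_manual_column_to_residue_mapping(self):
        t = make_template(6, 9)
        doms = {
            "a": make_domain("a", t.coords, t.sequence),
            "b": make_domain("b", t.coords[:5], t.sequence[:5]),
        }
        # b is gapped at column 2; conserved columns 2 and 4
        aln = FamilyAlignment("fam", ["a", "b"], ["AACDEF", "AA-DEF"[:6]])
        prof = conservation_scores(aln, threshold=0.0)
        prof.conserved_columns = set()
        prof = type(prof)(scores=prof.scores, threshold=0.0)
        # force exactly columns 2 and 4 conserved for the mapping check
        prof.conserved_columns = {2, 4}
        anns = conserved_to_sites(prof, aln, doms)
        by_id = {a.domain_id: a.residues for a in anns}
        assert by_id["a"] == {ResidueRef("A", 3, ""), ResidueRef("A", 5, "")}
        # b: column 2 is a gap; column 4 is b's 4th residue (A:4)
        assert by_id["b"] == {ResidueRef("A", 4, "")}

    def test_row_without_structure_skipped_with_warning(self):
        t = make_template(4, 10)
        doms = {"a": make_domain("a", t.coords, t.sequence)}
        aln = FamilyAlignment("fam", ["a", "ghost"], ["AAAA", "AAAA"])
        prof = conservation_scores(aln, threshold=0.0)
        with pytest.warns(UserWarning, match="ghost"):
            anns = conserved_to_sites(prof, aln, doms)
        assert {a.domain_id for a in anns} == {"a"}


class TestOverlapProportion:
    def _anns(self, domain, residues, site_type):
        return SiteAnnotation(domain, site_type,
                              {ResidueRef("A", r, "") for r in residues})

    def test_full_recovery(self):
        func = [self._anns("d", range(1, 11), "catalytic")]
        cons = [self._anns("d", range(1, 20), "conserved")]
        res = overlap_proportion(cons, func, "catalytic")
        assert res.fraction == 1.0

    def test_disjoint_sets(self):
        func = [self._anns("d", range(1, 11), "catalytic")]
        cons = [self._anns("d", range(50, 60), "conserved")]
        assert overlap_proportion(cons, func, "catalytic").fraction == 0.0

    def test_undefined_when_no_functional(self):
        cons = [self._anns("d", range(1, 5), "conserved")]
        res = overlap_proportion(cons, [], "catalytic")
        assert not res.defined and res.fraction == 0.0

    def test_planted_family_recovery(self):
        """Conserved columns coinciding with planted functional columns are
        recovered at the expected rate."""
        fracs = []
        for seed in range(10):
            aln, truth = make_conservation_family(100 + seed)
            prof = conservation_scores(aln)
            recovered = len(prof.conserved_columns & truth.functional_columns)
            fracs.append(recovered / len(truth.functional_columns))
        assert np.mean(fracs) > 0.6  # strong but imperfect recovery
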