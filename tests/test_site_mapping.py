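"""Representative selection, site projection, coverage and its filters."""

import numpy as np
import pytest

from siteplast import (
    CachingAligner,
    SingleClusterError,
    build_profile,
    coverage,
    flag_hub_superfamilies,
    heatmap_fractions,
    map_domain_sites,
    select_representative,
)
from siteplast.family_clustering import ClusterSet
from siteplast.pairwise_align import StructuralAlignment
from siteplast.site_mapping import RepresentativeProfile, colour_bin
from siteplast.structure_io import ResidueRef, SiteAnnotation
from siteplast.synthetic_data import make_template

from conftest import make_domain


def _clusters(*groups):
    return ClusterSet(kind="s60", clusters=[set(g) for g in groups], parameter=0.6)


class TestSelectRepresentative:
    def test_tie_break_smallest_id(self, template60):
        doms = {k: make_domain(k, template60.coords, template60.sequence)
                for k in ("d3", "d1", "d2")}
        rep = select_representative(doms, _clusters(["d1"], ["d2"], ["d3"]),
                                    CachingAligner())
        assert rep == "d1"

    def test_star_topology_central_domain_wins(self, template60, rng):
        doms = {"centre": make_domain(
            "centre", template60.coords + rng.normal(scale=0.1, size=(60, 3)),
            template60.sequence)}
        for k in range(3):
            doms[f"far{k}"] = make_domain(
                f"far{k}", template60.coords + rng.normal(scale=4.0, size=(60, 3)),
                template60.sequence)
        clusters = _clusters(*[[d] for d in doms])
        rep = select_representative(doms, clusters, CachingAligner())
        assert rep == "centre"

    def test_single_cluster_excluded(self, template60):
        doms = {"a": template60}
        with pytest.raises(SingleClusterError, match="single s60 cluster"):
            select_representative(doms, _clusters(["a"]), CachingAligner())


class TestMapDomainSites:
    def _pair(self):
        rep = make_domain("rep", make_template(20, 1).coords)
        mem = make_domain("mem", make_template(20, 2).coords)
        return rep, mem

    def test_mapped_through_pairs(self):
        rep, mem = self._pair()
        aln = StructuralAlignment("mem", "rep", [(7, 10), (8, 11)], rmsd=1.0)
        ann = SiteAnnotation("mem", "catalytic", {ResidueRef("A", 8, "")})  # pos 7
        assert map_domain_sites(rep, mem, aln, ann) == {10}

    def test_gap_aligned_residue_ignored(self):
        rep, mem = self._pair()
        aln = StructuralAlignment("mem", "rep", [(0, 0), (1, 1)], rmsd=1.0)
        ann = SiteAnnotation("mem", "catalytic", {ResidueRef("A", 8, "")})
        assert map_domain_sites(rep, mem, aln, ann) == set()

    def test_orientation_mirrored_internally(self):
        rep, mem = self._pair()
        aln = StructuralAlignment("rep", "mem", [(10, 7)], rmsd=1.0)
        ann = SiteAnnotation("mem", "catalytic", {ResidueRef("A", 8, "")})
        assert map_domain_sites(rep, mem, aln, ann) == {10}

    def test_self_mapping_identity(self):
        rep, _ = self._pair()
        aln = StructuralAlignment("rep", "rep", [(i, i) for i in range(20)], rmsd=0.0)
        ann = SiteAnnotation("rep", "catalytic",
                             {ResidueRef("A", 3, ""), ResidueRef("A", 5, ""),
                              ResidueRef("A", 9, "")})
        assert map_domain_sites(rep, rep, aln, ann) == {2, 4, 8}

    def test_wrong_domain_is_error(self):
        rep, mem = self._pair()
        aln = StructuralAlignment("mem", "rep", [(0, 0)], rmsd=0.0)
        ann = SiteAnnotation("other", "catalytic", {ResidueRef("A", 1, "")})
        with pytest.raises(ValueError, match="other"):
            map_domain_sites(rep, mem, aln, ann)


class TestBuildProfile:
    def test_union_over_members_matches_hand_enumeration(self):
        """Four members mapping onto a 6-residue representative: per-position
        contributor counts match manual union."""
        rep = make_domain("rep", make_template(6, 3).coords)
        members = {"rep": rep}
        alignments = {}
        for k in range(1, 5):
            dom = make_domain(f"d{k}", make_template(6, 3 + k).coords)
            members[f"d{k}"] = dom
            alignments[f"d{k}"] = StructuralAlignment(
                f"d{k}", "rep", [(i, i) for i in range(6)], rmsd=0.5)
        # d1 and d2 bind at rep positions {1,2}; d4 at {4}; d3 nothing
        anns = [
            SiteAnnotation("d1", "protein_protein",
                           {ResidueRef("A", 2, ""), ResidueRef("A", 3, "")}),
            SiteAnnotation("d2", "protein_protein",
                           {ResidueRef("A", 2, ""), ResidueRef("A", 3, "")}),
            SiteAnnotation("d4", "protein_protein", {ResidueRef("A", 5, "")}),
        ]
        prof = build_profile("SF", members, "rep", alignments, anns)
        counts = [len(s) for s in prof.contributors("protein_protein")]
        assert counts == [0, 2, 2, 0, 1, 0]

    def test_no_annotations_empty_sets(self):
        rep = make_domain("rep", make_template(5, 4).coords)
        prof = build_profile("SF", {"rep": rep}, "rep", {}, [])
        assert all(not s for s in prof.contributors("catalytic"))

    def test_annotated_member_without_alignment_is_error(self):
        rep = make_domain("rep", make_template(5, 4).coords)
        mem = make_domain("mem", make_template(5, 5).coords)
        ann = SiteAnnotation("mem", "catalytic", {ResidueRef("A", 1, "")})
        with pytest.raises(KeyError, match="mem"):
            build_profile("SF", {"rep": rep, "mem": mem}, "rep", {}, [ann])


def _profile(rep_length, by_domain, n_domains=4, s60=None):
    return RepresentativeProfile(
        superfamily_id="SF", representative_id="rep", rep_length=rep_length,
        n_domains=n_domains,
        by_domain={"protein_protein": by_domain},
        annotated_domains={"protein_protein": set(by_domain)},
        s60_assignment=s60)


class TestCoverage:
    def test_fraction_of_touched_positions(self):
        prof = _profile(100, {"d1": set(range(10)), "d2": set(range(5, 25))})
        res = coverage(prof, "protein_protein")
        assert res.coverage == pytest.approx(0.25)
        assert not res.excluded

    def test_rep_too_short_excluded(self):
        prof = _profile(99, {"d1": {0}})
        res = coverage(prof, "protein_protein")
        assert res.excluded and res.exclusion_reason == "rep_too_short"

    def test_dominance_strictly_greater(self):
        res51 = coverage(_profile(100, {"d1": set(range(51))}), "protein_protein")
        assert res51.excluded and res51.exclusion_reason == "single_domain_dominance"
        res50 = coverage(_profile(100, {"d1": set(range(50))}), "protein_protein")
        assert not res50.excluded

    def test_filters_can_be_disabled(self):
        prof = _profile(99, {"d1": set(range(60))})
        res = coverage(prof, "protein_protein",
                       apply_length_filter=False, apply_dominance_filter=False)
        assert not res.excluded

    def test_no_data_reported_as_zero(self):
        prof = _profile(100, {})
        res = coverage(prof, "protein_protein")
        assert res.coverage == 0.0 and not res.excluded

    def test_monotone_under_added_annotation(self, rng):
        """Adding a site never decreases coverage; dropping a member never
        increases any contributor set."""
        by_domain = {f"d{i}": set(map(int, rng.choice(100, size=8, replace=False)))
                     for i in range(5)}
        base = coverage(_profile(100, by_domain), "protein_protein").coverage
        grown = {k: set(v) for k, v in by_domain.items()}
        grown["d0"] |= {int(rng.integers(100))}
        assert coverage(_profile(100, grown), "protein_protein").coverage >= base
        shrunk = {k: v for k, v in by_domain.items() if k != "d3"}
        assert coverage(_profile(100, shrunk), "protein_protein").coverage <= base

    def test_union_matches_bruteforce_oracle(self, rng):
        for _ in range(20):
            n_mem = int(rng.integers(1, 10))
            length = int(rng.integers(20, 120))
            by_domain = {
                f"d{i}": set(map(int, rng.choice(
                    length, size=int(rng.integers(0, length // 2 + 1)),
                    replace=False)))
                for i in range(n_mem)}
            res = coverage(_profile(length, by_domain), "protein_protein",
                           apply_length_filter=False, apply_dominance_filter=False)
            oracle = len(set().union(*by_domain.values())) / length \
                if by_domain else 0.0
            assert res.coverage == pytest.approx(oracle)


class TestHeatmap:
    @pytest.mark.parametrize("fraction, colour", [
        (0.0, "grey"), (0.05, "blue"), (0.2, "green"), (0.39, "green"),
        (0.4, "yellow"), (0.7, "orange"), (0.8, "red"), (1.0, "red"),
    ])
    def test_colour_bins(self, fraction, colour):
        assert colour_bin(fraction) == colour

    def test_fractions_by_domain_denominator(self):
        prof = _profile(4, {"d1": {0, 1}, "d2": {1}}, n_domains=10)
        hm = heatmap_fractions(prof, "protein_protein", denominator="domains")
        np.testing.assert_allclose(hm.fractions, [0.1, 0.2, 0.0, 0.0])
        assert hm.bins == ["blue", "green", "grey", "grey"]

    def test_cluster_denominator(self):
        prof = _profile(3, {"d1": {0}, "d2": {0}}, n_domains=4,
                        s60={"d1": 0, "d2": 0, "d3": 1, "d4": 2})
        hm = heatmap_fractions(prof, "protein_protein", denominator="s60_clusters")
        np.testing.assert_allclose(hm.fractions, [1 / 3, 0.0, 0.0])


class TestHubs:
    @pytest.mark.parametrize("counts, expected", [
        ({"a": 3, "b": 12}, {"SF"}),
        ({"a": 9, "b": 9}, set()),
        ({"a": 10}, {"SF"}),  # "at least 10"
    ])
    def test_threshold(self, counts, expected):
        membership = {d: "SF" for d in counts}
        assert flag_hub_superfamilies(counts, membership) == expected
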