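"""Enrichment, rank-sum tests (with a full enumeration oracle), and the
coverage summary comparisons."""

import itertools
import math

import numpy as np
import pytest

from siteplast import (
    compare_diverse_vs_similar,
    enrichment,
    high_coverage_proportion,
    wilcoxon_rank_sum,
)
from siteplast.stats import (
    EnrichmentResult,
    average_by_superfamily,
    enrichment_sign_test,
    enrichment_test,
)


def rank_sum_p_enumeration(x, y, alternative="greater"):
    """Oracle: exact p by enumerating all rank assignments (tie-free)."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), len(x)):
        w = sum(combo)
        total += 1
        if alternative == "greater":
            count += w >= w_obs
        else:
            mu = len(x) * (n + 1) / 2
            count += abs(w - mu) >= abs(w_obs - mu) - 1e-12
    return count / total


class TestEnrichment:
    def test_subtraction(self):
        allr = set(range(10))
        res = enrichment({0, 1}, {0, 3, 4}, allr)  # Pc 0.5, Pa 0.3
        assert res.e == pytest.approx(res.pc - res.pa)
        res2 = enrichment({0, 1, 2, 3}, {0, 1, 8, 9}, set(range(20)))
        assert (res2.pc, res2.pa, res2.e) == (0.5, 0.2, pytest.approx(0.3))

    def test_degenerate_all_functional(self):
        allr = set(range(8))
        res = enrichment(allr, allr, allr)
        assert res.pc == 1.0 and res.pa == 1.0 and res.e == 0.0

    def test_empty_conserved_flagged(self):
        res = enrichment(set(), {1}, {1, 2})
        assert not res.defined and math.isnan(res.pc)

    def test_subset_violation_is_error(self):
        with pytest.raises(ValueError):
            enrichment({99}, {1}, {1, 2})

    def test_random_conserved_null_expectation(self, rng):
        """Uniformly random conserved sets give E ~ 0 in expectation."""
        allr = list(range(100))
        functional = set(range(30))
        es = []
        for _ in range(1000):
            conserved = set(rng.choice(allr, size=20, replace=False).tolist())
            es.append(enrichment(conserved, functional, set(allr)).e)
        assert abs(np.mean(es)) < 0.01


class TestWilcoxonRankSum:
    def test_extreme_separation_exact_p(self):
        out = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], "greater")
        assert out.method == "exact"
        assert out.p_value == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_identical_samples_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            out = wilcoxon_rank_sum([2, 2], [2, 2], "two_sided")
        assert out.p_value == 1.0

    def test_matches_enumeration_oracle(self, rng):
        """Exact p equals full rank-assignment enumeration for n <= 12."""
        for _ in range(30):
            nx_ = int(rng.integers(1, 7))
            ny_ = int(rng.integers(1, 13 - nx_))
            pooled = rng.choice(10_000, size=nx_ + ny_, replace=False) / 100.0
            x, y = pooled[:nx_].tolist(), pooled[nx_:].tolist()
            for alt in ("greater", "two_sided"):
                out = wilcoxon_rank_sum(x, y, alt)
                assert out.method == "exact"
                assert out.p_value == pytest.approx(
                    rank_sum_p_enumeration(x, y, alt), abs=1e-12)

    def test_exact_close_to_normal_approximation(self, rng):
        """At n = 30 per group the exact and approximate p agree within 0.02."""
        x = rng.normal(1.0, 1.0, size=30)
        y = rng.normal(0.0, 1.0, size=30)
        exact = wilcoxon_rank_sum(x.tolist(), y.tolist(), "greater",
                                  exact_max_n=40)
        approx = wilcoxon_rank_sum(x.tolist(), y.tolist(), "greater",
                                   exact_max_n=1)
        assert exact.method == "exact" and approx.method == "normal_approx"
        assert abs(exact.p_value - approx.p_value) < 0.02

    def test_ties_fall_back_to_approximation(self):
        out = wilcoxon_rank_sum([1, 2, 2], [2, 3, 4], "two_sided")
        assert out.method == "normal_approx"

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0], "greater")


class TestCompareDiverseVsSimilar:
    def test_planted_effect_detected(self, rng):
        """A stochastically larger diverse group rejects at 5% in >= 18/20
        seeded cohorts."""
        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            covs, flags = {}, {}
            for i in range(40):
                diverse = i < 20
                covs[f"sf{i}"] = float(np.clip(
                    r.normal(0.55 if diverse else 0.35, 0.12), 0, 1))
                flags[f"sf{i}"] = diverse
            out = compare_diverse_vs_similar(covs, flags)
            rejections += out.p_value < 0.05
        assert rejections >= 18

    def test_null_symmetric(self, rng):
        covs = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(size=30))}
        flags = {k: i < 15 for i, k in enumerate(covs)}
        two = compare_diverse_vs_similar(covs, flags, alternative="two_sided")
        assert two.p_value > 0.01  # no planted effect

    def test_label_swap_complements_one_sided_p(self, rng):
        covs = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(size=20))}
        flags = {k: i < 8 for i, k in enumerate(covs)}
        p_fwd = compare_diverse_vs_similar(covs, flags).p_value
        swapped = {k: not v for k, v in flags.items()}
        p_rev = compare_diverse_vs_similar(covs, swapped).p_value
        # one-sided p-values from the two labelings sit on opposite sides
        assert (p_fwd - 0.5) * (p_rev - 0.5) <= 0

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            compare_diverse_vs_similar({"a": 0.5}, {"a": True})


class TestEnrichmentAggregation:
    def test_average_by_superfamily_unweighted(self):
        results = [EnrichmentResult("f1", 0.6, 0.2, 0.4),
                   EnrichmentResult("f2", 0.4, 0.2, 0.2),
                   EnrichmentResult("f3", 0.9, 0.1, 0.8),
                   EnrichmentResult("f4", float("nan"), 0.3, float("nan"),
                                    defined=False)]
        mapping = {"f1": "SFa", "f2": "SFa", "f3": "SFb", "f4": "SFb"}
        agg = average_by_superfamily(results, mapping)
        assert [r.family_id for r in agg] == ["SFa", "SFb"]
        assert agg[0].pc == pytest.approx(0.5)
        assert agg[1].e == pytest.approx(0.8)  # undefined family dropped

    def test_planted_positive_enrichment_rejects(self, rng):
        """Conserved == functional structure gives E > 0 and a significant
        one-sided test in >= 18/20 replicates; random conserved sets keep
        the type-I rate near alpha."""
        def cohort(r, signal):
            results = []
            for i in range(15):
                allr = set(range(100))
                functional = set(r.choice(100, size=20, replace=False).tolist())
                if signal:
                    extra = set(r.choice(100, size=5, replace=False).tolist())
                    conserved = set(list(functional)[:15]) | extra
                else:
                    conserved = set(r.choice(100, size=20, replace=False).tolist())
                results.append(enrichment(conserved, functional, allr, f"f{i}"))
            return results

        rejections = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            out = enrichment_test(cohort(r, signal=True))
            es = [x.e for x in cohort(r, True)]
            rejections += out.p_value < 0.05 and np.mean(es) > 0
        assert rejections >= 18

        null_rejections = 0
        n_null = 200
        for seed in range(n_null):
            r = np.random.default_rng(10_000 + seed)
            out = enrichment_test(cohort(r, signal=False))
            null_rejections += out.p_value < 0.05
        assert 0.01 <= null_rejections / n_null <= 0.12

    def test_sign_test_option(self):
        results = [EnrichmentResult(f"f{i}", 0.5 + 0.02 * i, 0.2, 0.3 + 0.02 * i)
                   for i in range(10)]
        out = enrichment_sign_test(results)
        assert out.p_value < 0.01


class TestHighCoverageProportion:
    def test_counts(self):
        res = high_coverage_proportion([0.6, 0.4, 0.55])
        assert (res.n_above, res.n_total) == (2, 3)
        assert res.fraction == pytest.approx(2 / 3)

    def test_strict_inequality_at_half(self):
        assert high_coverage_proportion([0.5, 0.5]).n_above == 0

    def test_all_below(self):
        assert high_coverage_proportion([0.1, 0.2]).fraction == 0.0

    def test_order_invariant(self, rng):
        vals = rng.uniform(size=50).tolist()
        shuffled = list(vals)
        rng.shuffle(shuffled)
        assert high_coverage_proportion(vals).fraction == \
            high_coverage_proportion(shuffled).fraction

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            high_coverage_proportion([])
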