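"""Enrichment of functional residues among conserved residues, rank-sum
tests, and the summary comparisons built on coverage results.

The enrichment of one functional family is E = Pc - Pa, where Pc is the
proportion of conserved residues that are also functional and Pa the
proportion of all residues that are functional.  E > 0 means conservation
is informative about function in that family.  Significance is assessed
with a Wilcoxon rank-sum test over the Pc and Pa vectors (one-sided
"greater" by default); family-level enrichments can first be averaged to
superfamily level so that large superfamilies do not dominate the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class EnrichmentResult:
    family_id: str
    pc: float
    pa: float
    e: float
    defined: bool = True  # False when the family has no conserved residues


@dataclass
class TestOutcome:
    statistic: float  # rank-sum W of the first sample
    p_value: float
    method: str  # "exact" or "normal_approx"
    alternative: str  # "greater" or "two_sided"


def enrichment(conserved_residues: set, functional_residues: set,
               all_residues: set, family_id: str = "") -> EnrichmentResult:
    """E = Pc - Pa for one family.

    Pc = |conserved & functional| / |conserved|, Pa = |functional| / |all|.
    Both input sets must be subsets of ``all_residues``.  A family with no
    conserved residues has Pc undefined and is flagged for exclusion from
    averaging.
    """
    if not all_residues:
        raise ValueError("all_residues must be non-empty")
    if not conserved_residues <= all_residues:
        raise ValueError("conserved residues must be a subset of all residues")
    if not functional_residues <= all_residues:
        raise ValueError("functional residues must be a subset of all residues")
    pa = len(functional_residues) / len(all_residues)
    if not conserved_residues:
        return EnrichmentResult(family_id, float("nan"), pa, float("nan"),
                                defined=False)
    pc = len(conserved_residues & functional_residues) / len(conserved_residues)
    return EnrichmentResult(family_id, pc, pa, pc - pa)


_ALT = {"greater": "greater", "two_sided": "two-sided"}


def wilcoxon_rank_sum(sample_x: Sequence[float], sample_y: Sequence[float],
                      alternative: str = "greater",
                      exact_max_n: int = 25) -> TestOutcome:
    """Wilcoxon rank-sum (Mann-Whitney) test of x against y.

    The exact null distribution is enumerated when both samples have at
    most ``exact_max_n`` observations and the pooled values are tie-free;
    otherwise a normal approximation with tie correction and a 0.5
    continuity correction is used.  The statistic reported is the rank-sum
    W of the first sample.
    """
    if alternative not in _ALT:
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if np.ptp(pooled) == 0.0:
        warnings.warn("all values identical across both samples; p = 1",
                      stacklevel=2)
        return TestOutcome(w, 1.0, "normal_approx", alternative)
    tie_free = np.unique(pooled).size == pooled.size
    exact = tie_free and x.size <= exact_max_n and y.size <= exact_max_n
    res = sps.mannwhitneyu(x, y, alternative=_ALT[alternative],
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return TestOutcome(w, float(res.pvalue),
                       "exact" if exact else "normal_approx", alternative)


def enrichment_test(results: Iterable[EnrichmentResult],
                    alternative: str = "greater") -> TestOutcome:
    """Rank-sum test of the Pc values against the Pa values.

    Families with undefined Pc are excluded (and should be reported by the
    caller).
    """
    defined = [r for r in results if r.defined]
    if not defined:
        raise ValueError("no families with defined enrichment")
    return wilcoxon_rank_sum([r.pc for r in defined], [r.pa for r in defined],
                             alternative=alternative)


def enrichment_sign_test(results: Iterable[EnrichmentResult],
                         alternative: str = "greater") -> TestOutcome:
    """One-sample signed-rank test of the E values against zero (option)."""
    e = np.array([r.e for r in results if r.defined])
    if e.size < 1:
        raise ValueError("no families with defined enrichment")
    if np.all(e == 0):
        return TestOutcome(0.0, 1.0, "normal_approx", alternative)
    res = sps.wilcoxon(e, alternative=_ALT[alternative])
    return TestOutcome(float(res.statistic), float(res.pvalue),
                       "exact" if e.size <= 25 else "normal_approx", alternative)


def average_by_superfamily(results: Iterable[EnrichmentResult],
                           family_to_superfamily: Mapping[str, str],
                           ) -> list[EnrichmentResult]:
    """Unweighted mean of family-level Pc/Pa/E within each superfamily.

    Families with undefined Pc are dropped before averaging; superfamilies
    with no defined family disappear from the output.
    """
    groups: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        if not r.defined:
            continue
        sf = family_to_superfamily[r.family_id]
        groups.setdefault(sf, []).append(r)
    out = []
    for sf in sorted(groups):
        rs = groups[sf]
        pc = float(np.mean([r.pc for r in rs]))
        pa = float(np.mean([r.pa for r in rs]))
        out.append(EnrichmentResult(sf, pc, pa, pc - pa))
    return out


def compare_diverse_vs_similar(coverages: Mapping[str, float],
                               diversity_flags: Mapping[str, bool],
                               alternative: str = "greater") -> TestOutcome:
    """One-sided rank-sum of diverse-superfamily coverages vs the rest."""
    diverse = [coverages[s] for s in coverages if diversity_flags[s]]
    similar = [coverages[s] for s in coverages if not diversity_flags[s]]
    if not diverse or not similar:
        raise ValueError("both the diverse and the similar group must be non-empty")
    return wilcoxon_rank_sum(diverse, similar, alternative=alternative)


@dataclass
class HighCoverageResult:
    n_above: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_above / self.n_total


def high_coverage_proportion(coverages: Iterable[float],
                             threshold: float = 0.5) -> HighCoverageResult:
    """Proportion of superfamilies with coverage strictly above threshold."""
    values = list(coverages)
    if not values:
        raise ValueError("no coverage values given")
    return HighCoverageResult(sum(1 for v in values if v > threshold), len(values))
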