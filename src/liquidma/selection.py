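"""Selection tests against composition nulls, and fitness-per-mutation.

Under neutral placement, mutations fall on site classes in proportion to the
classes' sizes, so a 1-df chi-square goodness-of-fit of the observed
two-category split against the genome-composition proportions is the test
for selection. Fitness consequences are summarized as the per-line cost per
mutation, (W - 1)/burden, averaged over lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome import SiteClassTable

__all__ = [
    "RatioTestResult",
    "FitnessCostEstimate",
    "composition_ratio_test",
    "ns_s_test",
    "fitness_cost_per_mutation",
    "compare_treatments",
    "cv",
]


@dataclass(frozen=True)
class RatioTestResult:
    """Observed split, its composition-null expectation, and the chi-square test."""

    observed: tuple[int, int]
    expected_proportion_a: float
    chi2: float
    p: float
    observed_ratio: float | None

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not 0 <= self.p <= 1:
            raise ValueError("invalid chi2/p")


def composition_ratio_test(count_a: int, count_b: int,
                           sites_a: float, sites_b: float) -> RatioTestResult:
    """1-df chi-square of a two-category count split vs a site-size null.

    ``observed_ratio`` is count_a/count_b (None when count_b is 0). P-values
    are uncorrected, as is conventional for single planned contrasts.
    """
    if count_a < 0 or count_b < 0 or count_a + count_b == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    if sites_a <= 0 or sites_b <= 0:
        raise ValueError("site counts must be positive")
    total = count_a + count_b
    p_a = sites_a / (sites_a + sites_b)
    expected = np.array([total * p_a, total * (1 - p_a)])
    if expected.min() < 1:
        warnings.warn(
            f"expected cell count {expected.min():.3g} < 1; the chi-square "
            "approximation is unreliable at this sample size",
            stacklevel=2,
        )
    chi2_stat, p = stats.chisquare([count_a, count_b], f_exp=expected)
    ratio = count_a / count_b if count_b > 0 else None
    return RatioTestResult(
        observed=(count_a, count_b),
        expected_proportion_a=p_a,
        chi2=float(chi2_stat),
        p=float(p),
        observed_ratio=ratio,
    )


def ns_s_test(nonsyn_count: int, syn_count: int,
              site_table: SiteClassTable) -> RatioTestResult:
    """Nonsynonymous:synonymous placement test against the effective-site null."""
    return composition_ratio_test(
        nonsyn_count, syn_count,
        site_table.eff_nonsyn_sites, site_table.eff_syn_sites,
    )


@dataclass(frozen=True)
class FitnessCostEstimate:
    """Per-line fitness costs per mutation and their mean +/- SEM."""

    per_line: dict[str, float]
    mean: float
    sem: float | None


def fitness_cost_per_mutation(relative_fitness_by_line: Mapping[str, float],
                              mutation_burden_by_line: Mapping[str, float],
                              ) -> FitnessCostEstimate:
    """Average fitness cost per mutation, (W - 1)/burden per line.

    ``relative_fitness_by_line`` holds ancestor-normalized fitness W; the
    burden is the summed count of substitutions and indels. Lines with zero
    burden are excluded with a warning; line ids must match.
    """
    missing = set(relative_fitness_by_line) ^ set(mutation_burden_by_line)
    if missing:
        raise ValueError(f"line ids do not match between inputs: {sorted(missing)}")
    per_line: dict[str, float] = {}
    skipped = []
    for line_id, w in relative_fitness_by_line.items():
        burden = mutation_burden_by_line[line_id]
        if burden <= 0:
            skipped.append(line_id)
            continue
        per_line[line_id] = (w - 1.0) / burden
    if skipped:
        warnings.warn(f"lines with zero mutation burden excluded: {sorted(skipped)}",
                      stacklevel=2)
    if not per_line:
        raise ValueError("no lines with positive mutation burden")
    values = np.array(list(per_line.values()))
    sem = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else None
    return FitnessCostEstimate(per_line=per_line, mean=float(values.mean()), sem=sem)


def compare_treatments(values_a: Sequence[float], values_b: Sequence[float],
                       test: str = "t") -> tuple[float, float]:
    """Two-sided two-sample comparison between treatments.

    ``test="t"`` is the Welch (unequal-variance) t-test; ``test="mann_whitney"``
    is the Mann-Whitney U, exact for groups of up to 8 values and the
    continuity-corrected normal approximation otherwise. Returns
    (statistic, p); for the MWU the statistic is U for the first group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if test == "t":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        return float(stat), float(p)
    if test == "mann_whitney":
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn("both samples are identical constants; U test degenerate, p = 1",
                          stacklevel=2)
            return float(a.size * b.size / 2.0), 1.0
        method = "exact" if max(a.size, b.size) <= 8 and not _has_ties(a, b) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}; use 't' or 'mann_whitney'")


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size < pooled.size


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample standard deviation over the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a CV")
    mean = x.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)
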