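"""Generation counting, mutation-rate estimation and spectrum summaries.

The MA estimator is arithmetic: mutations accumulate clock-like through
single-cell bottlenecks, so the per-site per-generation rate is

    mu = (mutations per line) / (transfers x generations-per-transfer x sites)

with generations per transfer read off the census as log2(N_final/N_initial).
Per-class rates divide each class's summed count by the number of sites of
the matching origin pair (A:T classes by A+T sites, G:C classes by G+C
sites) times total generations, with 95% CIs from the normal approximation
to the Poisson count (the "pois.approx" convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import SiteClassTable
from .mutio import BPS_CLASSES, MutationRecord, SpectrumTable

__all__ = [
    "LineSummary",
    "RateEstimate",
    "ClassRate",
    "generations_per_transfer",
    "two_point_mean_generations",
    "mutation_rate",
    "mutation_rate_lines",
    "class_rates",
    "spectrum_ratios",
    "line_summaries_from_tables",
    "read_line_summaries",
    "write_line_summaries",
    "DEFAULT_GENOME_SIZE",
]

#: Default denominator genome size (bp) for rate estimates.
DEFAULT_GENOME_SIZE = 4.6e6

_AT_CLASSES = ("A:T->G:C", "A:T->C:G", "A:T->T:A")


@dataclass(frozen=True)
class LineSummary:
    """Per-line mutation burden and division count for one treatment."""

    line_id: str
    bps_count: int
    indel_count: int
    total_generations: float
    treatment: str = "liquid"

    def __post_init__(self) -> None:
        if self.bps_count < 0 or self.indel_count < 0:
            raise ValueError("mutation counts must be nonnegative")
        if self.total_generations <= 0:
            raise ValueError("total_generations must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """A mutation rate (events/site/generation) with its SEM when available."""

    rate: float
    sem: float | None
    n_lines: int

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be nonnegative")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be nonnegative")


@dataclass(frozen=True)
class ClassRate:
    """Per-class rate with Poisson-normal 95% CI, plus the raw count."""

    bps_class: str
    rate: float
    ci_low: float
    ci_high: float
    count: int

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.rate <= self.ci_high:
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket rate {self.rate}"
            )


def generations_per_transfer(n_final: float, n_initial: float = 1.0) -> float:
    """Cell divisions implied by growth from ``n_initial`` to ``n_final``."""
    if n_initial < 1 or n_final < n_initial:
        raise ValueError(
            f"need n_final >= n_initial >= 1, got n_final={n_final}, n_initial={n_initial}"
        )
    return math.log2(n_final / n_initial)


def two_point_mean_generations(g_day1: float, g_final: float) -> float:
    """Mean of start-of-experiment and end-of-experiment division estimates.

    The census at the end of an MA differs from day 1 because fitness
    declines; averaging the two point estimates is the standard correction.
    """
    if g_day1 <= 0 or g_final <= 0:
        raise ValueError("generation estimates must be positive")
    return 0.5 * (g_day1 + g_final)


def mutation_rate(mean_count_per_line: float, transfers: float,
                  gens_per_transfer: float, sites: float = DEFAULT_GENOME_SIZE,
                  ) -> RateEstimate:
    """Rate from a mean per-line burden and experiment-level denominators."""
    if mean_count_per_line < 0:
        raise ValueError("mean count must be nonnegative")
    if transfers <= 0 or gens_per_transfer <= 0 or sites <= 0:
        raise ValueError("transfers, generations and sites must all be positive")
    rate = mean_count_per_line / (transfers * gens_per_transfer * sites)
    return RateEstimate(rate=rate, sem=None, n_lines=0)


def mutation_rate_lines(lines: Sequence[LineSummary],
                        sites: float = DEFAULT_GENOME_SIZE,
                        kind: str = "bps") -> RateEstimate:
    """Per-line rate estimator: mean of per-line rates, SEM = sd/sqrt(n).

    Each line's rate uses its own realized total generations, so lines that
    grew more divide their burden by a larger denominator.
    """
    if not lines:
        raise ValueError("no line summaries supplied")
    if sites <= 0:
        raise ValueError("sites must be positive")
    if kind not in ("bps", "indel"):
        raise ValueError(f"kind must be 'bps' or 'indel', got {kind!r}")
    counts = np.array([ls.bps_count if kind == "bps" else ls.indel_count
                       for ls in lines], dtype=float)
    gens = np.array([ls.total_generations for ls in lines], dtype=float)
    per_line = counts / (gens * sites)
    sem = float(np.std(per_line, ddof=1) / math.sqrt(len(lines))) if len(lines) > 1 else None
    return RateEstimate(rate=float(per_line.mean()), sem=sem, n_lines=len(lines))


def class_rates(spectrum: SpectrumTable, site_table: SiteClassTable,
                total_generations_all_lines: float,
                method: str = "approx") -> list[ClassRate]:
    """Per-class rates against origin-pair site denominators.

    ``method="approx"`` gives the Poisson-normal 95% CI, count +/- 1.96*sqrt(count),
    divided by the shared denominator and floored at 0 (a zero count yields the
    degenerate interval (0, 0)). ``method="exact"`` substitutes Garwood
    chi-square intervals.
    """
    if total_generations_all_lines <= 0:
        raise ValueError("total generations must be positive")
    if site_table.at_sites <= 0 or site_table.gc_sites <= 0:
        raise ValueError("site table must have positive AT and GC site counts")
    if method not in ("approx", "exact"):
        raise ValueError(f"unknown CI method {method!r}")
    out = []
    for cls in BPS_CLASSES:
        sites = site_table.at_sites if cls in _AT_CLASSES else site_table.gc_sites
        denom = sites * total_generations_all_lines
        count = spectrum.count(cls)
        if method == "approx":
            half = 1.96 * math.sqrt(count)
            lo, hi = max(0.0, count - half), count + half
        else:
            from scipy.stats import chi2
            lo = 0.0 if count == 0 else chi2.ppf(0.025, 2 * count) / 2.0
            hi = chi2.ppf(0.975, 2 * (count + 1)) / 2.0
        out.append(ClassRate(bps_class=cls, rate=count / denom,
                             ci_low=lo / denom, ci_high=hi / denom, count=count))
    return out


def spectrum_ratios(spectrum: SpectrumTable,
                    other: SpectrumTable | None = None) -> dict:
    """Transition skew and, given two spectra, per-class contrasts.

    The transition skew is the count ratio A:T->G:C over G:C->A:T. With a
    second spectrum (convention: ``spectrum`` = reference, ``other`` =
    comparison), per-class differences are ``other - spectrum`` and percent
    changes are relative to the reference; a zero reference count flags the
    percent change as undefined (None).
    """
    def _skew(s: SpectrumTable) -> float | None:
        denom = s.count("G:C->A:T")
        return None if denom == 0 else s.count("A:T->G:C") / denom

    result: dict = {"transition_skew": _skew(spectrum)}
    if other is not None:
        result["transition_skew_other"] = _skew(other)
        diffs = {}
        pct = {}
        for cls in BPS_CLASSES:
            a, b = spectrum.count(cls), other.count(cls)
            diffs[cls] = b - a
            pct[cls] = None if a == 0 else 100.0 * (b - a) / a
        result["difference"] = diffs
        result["percent_change"] = pct
    return result


# ---------------------------------------------------------------------------
# assembling line summaries from pipeline tables
# ---------------------------------------------------------------------------

def line_summaries_from_tables(records: Iterable[MutationRecord],
                               cfu: pd.DataFrame) -> list[LineSummary]:
    """Join a mutation table with per-line per-day CFU counts.

    ``cfu`` needs columns line_id, day, treatment, cfu_per_ml. Each line's
    total generations is the sum over days of log2(cfu), exactly the
    census-based estimate the analysis assumes; its burden is its record
    count split by BPS/indel.
    """
    required = {"line_id", "day", "treatment", "cfu_per_ml"}
    missing = required - set(cfu.columns)
    if missing:
        raise ValueError(f"CFU table missing columns: {sorted(missing)}")
    if (cfu["cfu_per_ml"] <= 0).any():
        raise ValueError("CFU counts must be positive")
    bps: dict[str, int] = {}
    indels: dict[str, int] = {}
    for rec in records:
        d = indels if rec.is_indel else bps
        d[rec.line_id] = d.get(rec.line_id, 0) + 1
    summaries = []
    for line_id, group in cfu.groupby("line_id", sort=True):
        gens = float(np.log2(group["cfu_per_ml"].to_numpy(dtype=float)).sum())
        treatment = str(group["treatment"].iloc[0])
        summaries.append(LineSummary(
            line_id=str(line_id),
            bps_count=bps.get(str(line_id), 0),
            indel_count=indels.get(str(line_id), 0),
            total_generations=gens,
            treatment=treatment,
        ))
    return summaries


_LS_COLUMNS = ("line_id", "treatment", "bps_count", "indel_count", "total_generations")


def write_line_summaries(lines: Sequence[LineSummary], path: str | Path) -> None:
    pd.DataFrame(
        [(ls.line_id, ls.treatment, ls.bps_count, ls.indel_count, ls.total_generations)
         for ls in lines],
        columns=list(_LS_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def read_line_summaries(path: str | Path) -> list[LineSummary]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_LS_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"line summary table missing columns: {sorted(missing)}")
    return [
        LineSummary(line_id=str(r.line_id), bps_count=int(r.bps_count),
                    indel_count=int(r.indel_count),
                    total_generations=float(r.total_generations),
                    treatment=str(r.treatment))
        for r in frame.itertuples(index=False)
    ]
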