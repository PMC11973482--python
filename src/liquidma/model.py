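"""Model-object front end: build an MA analysis from tables, fit, summarize.

:class:`MAExperiment` collects the inputs of a mutation-accumulation
analysis (mutation records, per-line summaries, optionally a site-class
table for the composition nulls); :meth:`MAExperiment.fit` returns an
:class:`MAResults` carrying per-treatment burden and rate estimates with
SEMs, mutation spectra with contrasts, per-class rates with Poisson CIs,
and — when annotations and a site table are present — the chi-square
placement tests. ``summary()`` renders the experiment-summary and spectrum
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import SiteClassTable, expected_ratios
from .mutio import BPS_CLASSES, MutationRecord, SpectrumTable, exclude_lines, spectrum_counts
from .rates import (DEFAULT_GENOME_SIZE, ClassRate, LineSummary, RateEstimate,
                    class_rates, mutation_rate_lines, spectrum_ratios)
from .selection import RatioTestResult, composition_ratio_test, ns_s_test

__all__ = ["MAExperiment", "MAResults", "TreatmentFit"]


@dataclass
class TreatmentFit:
    """Fitted quantities for one treatment arm."""

    treatment: str
    n_lines: int
    mean_bps: float
    sem_bps: float | None
    mean_indel: float
    sem_indel: float | None
    mean_gens_per_transfer: float
    bps_rate: RateEstimate
    indel_rate: RateEstimate
    spectrum: SpectrumTable
    class_rates: list[ClassRate] | None = None
    genic_test: RatioTestResult | None = None
    indel_genic_test: RatioTestResult | None = None
    ns_s: RatioTestResult | None = None


class MAExperiment:
    """A mutation-accumulation experiment ready to be fitted.

    Parameters
    ----------
    mutations : sequence of MutationRecord
        Final mutation calls, optionally annotated with genic/effect labels.
    lines : sequence of LineSummary
        Per-line burden and realized generations, one per MA line.
    site_table : SiteClassTable, optional
        Genome composition; enables per-class rates and placement tests.
    genome_size : float
        Denominator site count for genome-wide rates (bp).
    transfers : int
        Number of daily transfers, used to report generations per transfer.
    exclude : sequence of str
        Line ids dropped from every estimate (e.g. hypermutators).
    """

    def __init__(self, mutations: Sequence[MutationRecord],
                 lines: Sequence[LineSummary],
                 site_table: SiteClassTable | None = None,
                 genome_size: float = DEFAULT_GENOME_SIZE,
                 transfers: int = 20,
                 exclude: Sequence[str] = ()) -> None:
        self.mutations = exclude_lines(mutations, exclude)
        self.lines = [ls for ls in lines if ls.line_id not in set(exclude)]
        if not self.lines:
            raise ValueError("no lines left to analyse")
        self.site_table = site_table
        self.genome_size = float(genome_size)
        self.transfers = int(transfers)
        self.excluded = tuple(exclude)

    @classmethod
    def from_tables(cls, mutation_tsv: str | Path, lines_tsv: str | Path,
                    site_tsv: str | Path | None = None, **kwargs) -> "MAExperiment":
        from .mutio import read_mutation_table
        from .rates import read_line_summaries
        site = SiteClassTable.from_tsv(site_tsv) if site_tsv else None
        return cls(read_mutation_table(mutation_tsv),
                   read_line_summaries(lines_tsv), site_table=site, **kwargs)

    @classmethod
    def from_simulation(cls, result, **kwargs) -> "MAExperiment":
        """Build directly from a :class:`liquidma.simulate.ExperimentResult`."""
        from .rates import line_summaries_from_tables
        records = result.mutation_records()
        lines = line_summaries_from_tables(records, result.cfu)
        kwargs.setdefault("transfers", result.config.transfers)
        kwargs.setdefault("genome_size", result.config.genome_length)
        return cls(records, lines, **kwargs)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "MAResults":
        treatments = sorted({ls.treatment for ls in self.lines})
        fits = {}
        for treatment in treatments:
            fits[treatment] = self._fit_treatment(treatment)
        contrasts = None
        if len(treatments) == 2:
            a, b = treatments
            contrasts = spectrum_ratios(fits[a].spectrum, fits[b].spectrum)
        ratios = expected_ratios(self.site_table) if self.site_table else None
        return MAResults(model=self, treatments=fits, spectrum_contrast=contrasts,
                         null_ratios=ratios)

    def _fit_treatment(self, treatment: str) -> TreatmentFit:
        lines = [ls for ls in self.lines if ls.treatment == treatment]
        muts = [m for m in self.mutations
                if m.line_id in {ls.line_id for ls in lines}]
        bps_counts = np.array([ls.bps_count for ls in lines], dtype=float)
        ind_counts = np.array([ls.indel_count for ls in lines], dtype=float)
        n = len(lines)

        def _sem(x: np.ndarray) -> float | None:
            return float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else None

        spectrum = spectrum_counts(muts)
        fit = TreatmentFit(
            treatment=treatment,
            n_lines=n,
            mean_bps=float(bps_counts.mean()),
            sem_bps=_sem(bps_counts),
            mean_indel=float(ind_counts.mean()),
            sem_indel=_sem(ind_counts),
            mean_gens_per_transfer=float(np.mean(
                [ls.total_generations / self.transfers for ls in lines])),
            bps_rate=mutation_rate_lines(lines, self.genome_size, kind="bps"),
            indel_rate=mutation_rate_lines(lines, self.genome_size, kind="indel"),
            spectrum=spectrum,
        )
        if self.site_table is not None:
            total_gens = float(sum(ls.total_generations for ls in lines))
            fit.class_rates = class_rates(spectrum, self.site_table, total_gens)
            fit.genic_test = self._placement_test(muts, indels=False)
            fit.indel_genic_test = self._placement_test(muts, indels=True)
            fit.ns_s = self._ns_s_test(muts)
        return fit

    def _placement_test(self, muts, indels: bool) -> RatioTestResult | None:
        sub = [m for m in muts if m.is_indel == indels and m.genic]
        if not sub:
            return None
        intra = sum(m.genic == "intragenic" for m in sub)
        return composition_ratio_test(intra, len(sub) - intra,
                                      self.site_table.coding_sites,
                                      self.site_table.noncoding_sites)

    def _ns_s_test(self, muts) -> RatioTestResult | None:
        ns = sum(m.effect == "nonsynonymous" for m in muts if not m.is_indel)
        s = sum(m.effect == "synonymous" for m in muts if not m.is_indel)
        if ns + s == 0:
            return None
        return ns_s_test(ns, s, self.site_table)


@dataclass
class MAResults:
    """Fitted estimates, spectra, contrasts and diagnostics of an MA analysis."""

    model: MAExperiment
    treatments: dict[str, TreatmentFit]
    spectrum_contrast: dict | None = None
    null_ratios: object | None = None

    # -- tabular views ------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for t, f in self.treatments.items():
            rows.append({
                "treatment": t,
                "sample_size": f.n_lines,
                "mean_bps_per_line": f.mean_bps,
                "sem_bps_per_line": f.sem_bps,
                "mean_indel_per_line": f.mean_indel,
                "sem_indel_per_line": f.sem_indel,
                "mean_generations_per_transfer": f.mean_gens_per_transfer,
                "bps_rate_per_site_per_gen": f.bps_rate.rate,
                "bps_rate_sem": f.bps_rate.sem,
                "indel_rate_per_site_per_gen": f.indel_rate.rate,
                "indel_rate_sem": f.indel_rate.sem,
            })
        return pd.DataFrame(rows)

    def spectrum_frame(self) -> pd.DataFrame:
        frames = []
        for t, f in self.treatments.items():
            frame = f.spectrum.to_frame()
            frame.insert(0, "treatment", t)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        """Human-readable experiment summary (rates shown in units of 1e-8)."""
        out = ["MA experiment summary", "=" * 72]
        header = (f"{'Treatment':<9}{'n':>4}{'BPS/line (SEM)':>20}"
                  f"{'indel/line (SEM)':>19}{'gens/transfer':>15}"
                  f"{'BPS rate':>12}{'indel rate':>12}")
        out.append(header)
        for t, f in self.treatments.items():
            sem_b = f"(±{f.sem_bps:.2f})" if f.sem_bps is not None else ""
            sem_i = f"(±{f.sem_indel:.2f})" if f.sem_indel is not None else ""
            out.append(
                f"{t:<9}{f.n_lines:>4}"
                f"{f.mean_bps:>12.1f} {sem_b:<8}"
                f"{f.mean_indel:>9.1f} {sem_i:<8}"
                f"{f.mean_gens_per_transfer:>12.1f}"
                f"{f.bps_rate.rate * 1e8:>11.2f}e-8"
                f"{f.indel_rate.rate * 1e8:>10.2f}e-8"
            )
        out.append("")
        out.append("Mutation spectrum (count, frequency)")
        out.append(f"{'class':<12}" + "".join(f"{t:>20}" for t in self.treatments))
        for cls in BPS_CLASSES:
            cells = []
            for f in self.treatments.values():
                freq = (f"{f.spectrum.frequency(cls):.3f}"
                        if f.spectrum.frequencies else "undef")
                cells.append(f"{f.spectrum.count(cls):>12} {freq:>7}")
            out.append(f"{cls:<12}" + "".join(cells))
        if self.spectrum_contrast and self.spectrum_contrast.get("difference"):
            out.append("")
            out.append("Between-treatment spectrum contrast (second - first treatment):")
            for cls in BPS_CLASSES:
                diff = self.spectrum_contrast["difference"][cls]
                pct = self.spectrum_contrast["percent_change"][cls]
                pct_s = f"{pct:+.0f}%" if pct is not None else "undef"
                out.append(f"  {cls:<12} diff {diff:+5d}  change {pct_s}")
        if self.null_ratios is not None:
            out.append("")
            out.append(
                f"Null placement ratios: coding:noncoding = "
                f"{self.null_ratios.coding_noncoding:.2f}, "
                f"nonsyn:syn = {self.null_ratios.nonsyn_syn:.2f}"
            )
            for t, f in self.treatments.items():
                if f.genic_test is not None:
                    r = f.genic_test.observed_ratio
                    out.append(
                        f"  {t} BPS intragenic:intergenic = "
                        f"{r:.2f} (chi2={f.genic_test.chi2:.2f}, p={f.genic_test.p:.3g})"
                        if r is not None else
                        f"  {t} BPS placement test: chi2={f.genic_test.chi2:.2f}"
                    )
                if f.ns_s is not None and f.ns_s.observed_ratio is not None:
                    out.append(
                        f"  {t} nonsyn:syn = {f.ns_s.observed_ratio:.2f} "
                        f"(chi2={f.ns_s.chi2:.2f}, p={f.ns_s.p:.3g})"
                    )
        return "\n".join(out)

    # -- plotting -----------------------------------------------------------

    def plot_spectrum(self, ax=None):
        """Grouped bar chart of per-class frequencies by treatment."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        width = 0.8 / max(len(self.treatments), 1)
        x = np.arange(len(BPS_CLASSES))
        for j, (t, f) in enumerate(self.treatments.items()):
            freqs = [f.spectrum.frequency(c) if f.spectrum.frequencies else 0.0
                     for c in BPS_CLASSES]
            ax.bar(x + j * width, freqs, width=width, label=t)
        ax.set_xticks(x + width * (len(self.treatments) - 1) / 2)
        ax.set_xticklabels(BPS_CLASSES, rotation=45, ha="right")
        ax.set_ylabel("frequency")
        ax.legend()
        return ax
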