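"""Forward simulation of liquid and plate mutation-accumulation experiments.

Each MA line is a lineage passed through daily single-cell bottlenecks. A
transfer grows the founder to a stochastic final census (lognormal, with a
treatment-specific coefficient of variation: colonies on agar vary far more
than 1 mL liquid cultures), accumulates Poisson mutation input proportional
to realized cell divisions, and bottlenecks:

* the liquid design inoculates rows of a deep-well plate at decreasing
  expected cells per well (Poisson occupancy), and picks the leftmost turbid
  well of the most dilute turbid row, so the next founder is usually a
  single cell;
* the plate design picks one colony, always a single founder cell.

Selection between bottlenecks is a branching-process thinning: a mutation
with fitness effect s, arising at a uniform time within the transfer, is
transmitted with probability min(1, exp(s*G/2)); lethal mutations are never
transmitted. Outputs are the exact tables the analysis modules read:
mutation TSV, per-line per-day CFU TSV, and plate-reader growth-curve TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import BASES, COMPLEMENT, GeneAnnotation, Genome
from .mutio import BPS_CLASSES, MutationRecord, records_to_frame
from .growth import CURVE_COLUMNS

__all__ = [
    "DilutionDesign",
    "DFE",
    "NFinalModel",
    "SimulationConfig",
    "LineHistory",
    "TransferOutcome",
    "ExperimentResult",
    "FailedTransfer",
    "simulate_dilution_bottleneck",
    "inoculate_row",
    "simulate_transfer",
    "simulate_experiment",
    "simulate_growth_curves",
    "harmonic_mean_popsize",
    "MMR_SPECTRUM",
]

#: Default substitution spectrum: the MMR-deficient E. coli spectrum, heavily
#: skewed to A:T->G:C transitions (normalized liquid-treatment class counts).
MMR_SPECTRUM = tuple(c / 1229.0 for c in (995, 198, 12, 15, 5, 4))

_CLASS_REF = {  # purine representative of each class: ref base -> alt base
    "A:T->G:C": ("A", "G"),
    "G:C->A:T": ("G", "A"),
    "A:T->C:G": ("A", "C"),
    "A:T->T:A": ("A", "T"),
    "G:C->T:A": ("G", "T"),
    "G:C->C:G": ("G", "C"),
}


class FailedTransfer(RuntimeError):
    """All wells of a serial dilution stayed clear; the transfer failed."""


@dataclass(frozen=True)
class DilutionDesign:
    """Rows of a deep-well serial dilution: (expected cells per well, wells).

    Rows are ordered from most to least concentrated; lambda values must be
    strictly decreasing. ``nominal_census`` (cells/mL), when set, scales the
    lambdas linearly with the source culture's census, so a weak culture
    seeds fewer cells. ``turbidity_threshold`` is the minimum founder count
    that produces visible growth.
    """

    rows: tuple[tuple[float, int], ...]
    turbidity_threshold: int = 1
    nominal_census: float | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("a dilution design needs at least one row")
        lams = [lam for lam, _ in self.rows]
        if any(l <= 0 for l in lams):
            raise ValueError("expected cells per well must be positive")
        if any(b >= a for a, b in zip(lams, lams[1:])):
            raise ValueError(f"row lambdas must be strictly decreasing, got {lams}")
        if any(w < 1 for _, w in self.rows):
            raise ValueError("each row needs at least one well")
        if self.turbidity_threshold < 1:
            raise ValueError("turbidity threshold must be >= 1 cell")

    @classmethod
    def default_liquid(cls) -> "DilutionDesign":
        # three 8-well rows at one order of magnitude of dilution: 20 uL of a
        # 1e-7 dilution, then 50 uL and 20 uL of a 1e-8 dilution of a
        # ~1e9 CFU/mL overnight culture
        return cls(rows=((2.0, 8), (0.5, 8), (0.2, 8)), nominal_census=1e9)


def inoculate_row(lam: float, wells: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson founder counts for one row of wells."""
    if lam <= 0 or wells < 1:
        raise ValueError("need positive lambda and at least one well")
    return rng.poisson(lam, size=wells)


def simulate_dilution_bottleneck(design: DilutionDesign, census: float,
                                 rng: np.random.Generator,
                                 ) -> tuple[int, int, int]:
    """Run one serial dilution and pick the next founder well.

    Every well's founder count is Poisson at its row's (census-scaled)
    lambda. Among turbid wells (count >= threshold) the well in the lowest-
    lambda row wins; within a row, the leftmost turbid well. Returns
    (founder_count, row_index, well_index); raises :class:`FailedTransfer`
    if every well stays clear.
    """
    if census <= 0:
        raise ValueError("census must be positive")
    scale = census / design.nominal_census if design.nominal_census else 1.0
    counts = [inoculate_row(lam * scale, wells, rng) for lam, wells in design.rows]
    for row_index in range(len(counts) - 1, -1, -1):
        turbid = np.flatnonzero(counts[row_index] >= design.turbidity_threshold)
        if turbid.size:
            well_index = int(turbid[0])
            return int(counts[row_index][well_index]), row_index, well_index
    raise FailedTransfer("no turbid well in any dilution row")


@dataclass(frozen=True)
class DFE:
    """Distribution of fitness effects of new mutations.

    Deleterious effects are exponential with mean ``deleterious_mean_effect``;
    a ``lethal_fraction`` of mutations kill the carrier lineage outright and
    a ``beneficial_fraction`` get positive exponential effects. Indel effects
    are scaled up by ``indel_effect_multiplier`` (indels are more disruptive
    than substitutions). The all-zero default of each sampling branch makes
    ``DFE()`` with zero fractions and zero mean a strictly neutral model.
    """

    lethal_fraction: float = 0.0
    deleterious_mean_effect: float = 0.0
    beneficial_fraction: float = 0.0
    beneficial_mean_effect: float = 0.001
    indel_effect_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.lethal_fraction <= 1 or not 0 <= self.beneficial_fraction <= 1:
            raise ValueError("DFE fractions must lie in [0, 1]")
        if self.lethal_fraction + self.beneficial_fraction > 1:
            raise ValueError("lethal_fraction + beneficial_fraction must be <= 1")
        if self.deleterious_mean_effect < 0 or self.beneficial_mean_effect < 0:
            raise ValueError("mean effects must be nonnegative")

    @classmethod
    def neutral(cls) -> "DFE":
        return cls()

    @classmethod
    def default_mmr(cls) -> "DFE":
        # modest purifying pressure consistent with a per-mutation fitness
        # cost on the order of -1e-3, with indels more disruptive
        return cls(lethal_fraction=0.005, deleterious_mean_effect=0.001,
                   beneficial_fraction=0.001, beneficial_mean_effect=0.001,
                   indel_effect_multiplier=3.0)


@dataclass(frozen=True)
class NFinalModel:
    """Lognormal end-of-day census model: median cells and CV per treatment."""

    treatment: str
    median_cells: float
    cv: float

    def __post_init__(self) -> None:
        if self.treatment not in ("liquid", "plate"):
            raise ValueError(f"treatment must be 'liquid' or 'plate', got {self.treatment!r}")
        if self.median_cells < 2:
            raise ValueError("median final census must be at least 2 cells")
        if self.cv <= 0:
            raise ValueError("CV must be positive")

    @classmethod
    def default(cls, treatment: str) -> "NFinalModel":
        # liquid: 1 mL deep-well cultures reach ~1e9 cells (29.9 doublings)
        # with little variation; plate colonies reach ~1.25e8 (26.9 doublings)
        # with much higher variation from colony crowding
        if treatment == "liquid":
            return cls("liquid", median_cells=1e9, cv=0.12)
        return cls("plate", median_cells=1.25e8, cv=0.5)

    @property
    def sigma_log(self) -> float:
        return math.sqrt(math.log1p(self.cv ** 2))


@dataclass
class SimulationConfig:
    """Everything defining one simulated MA experiment."""

    genome_length: int = 4_600_000
    genome: Genome | None = None
    annotation: GeneAnnotation | None = None
    mu_bps: float = 2.8e-8
    mu_indel: float = 6.5e-9
    spectrum: tuple[float, ...] = MMR_SPECTRUM
    dfe: DFE = field(default_factory=DFE.default_mmr)
    treatment: str = "liquid"
    n_final: NFinalModel | None = None
    dilution: DilutionDesign | None = None
    transfers: int = 20
    lines: int = 16
    seed: int = 0
    max_transfer_retries: int = 10

    def __post_init__(self) -> None:
        if self.genome is not None:
            self.genome_length = len(self.genome)
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        for name in ("mu_bps", "mu_indel"):
            rate = getattr(self, name)
            if not 0 <= rate < 1e-3:
                raise ValueError(f"{name}={rate} outside [0, 1e-3)")
        if len(self.spectrum) != len(BPS_CLASSES):
            raise ValueError(f"spectrum needs {len(BPS_CLASSES)} probabilities")
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError(f"spectrum sums to {sum(self.spectrum)}, not 1")
        if any(p < 0 for p in self.spectrum):
            raise ValueError("spectrum probabilities must be nonnegative")
        if self.treatment not in ("liquid", "plate"):
            raise ValueError(f"treatment must be 'liquid' or 'plate', got {self.treatment!r}")
        if self.n_final is None:
            self.n_final = NFinalModel.default(self.treatment)
        if self.treatment == "liquid" and self.dilution is None:
            self.dilution = DilutionDesign.default_liquid()
        if self.transfers < 1 or self.lines < 1:
            raise ValueError("need at least one transfer and one line")
        self._at_positions: np.ndarray | None = None
        self._gc_positions: np.ndarray | None = None
        self._coding_index = None
        if self.genome is not None:
            arr = np.frombuffer(self.genome.sequence.encode(), dtype=np.uint8)
            is_at = (arr == ord("A")) | (arr == ord("T"))
            self._at_positions = np.flatnonzero(is_at) + 1
            self._gc_positions = np.flatnonzero(~is_at) + 1
            if self.annotation is not None:
                from .genome import CodingIndex
                self._coding_index = CodingIndex(self.genome, self.annotation)


@dataclass(frozen=True)
class SimMutation:
    """One transmitted mutation with its fitness effect and provenance."""

    position: int
    ref: str
    alt: str
    is_indel: bool
    s: float
    transfer: int = 0


@dataclass(frozen=True)
class TransferOutcome:
    mutations: tuple[SimMutation, ...]
    n_final: float
    generations: float
    founder_count: int = 1


@dataclass
class LineHistory:
    """Per-transfer record of one MA line."""

    line_id: str
    treatment: str
    founder_counts: list[int] = field(default_factory=list)
    n_finals: list[float] = field(default_factory=list)
    generations: list[float] = field(default_factory=list)
    mutations: list[SimMutation] = field(default_factory=list)
    fitness: float = 1.0


def _draw_bps(config: SimulationConfig, rng: np.random.Generator,
              transfer: int, n: int) -> list[SimMutation]:
    if n == 0:
        return []
    classes = rng.choice(len(BPS_CLASSES), size=n, p=np.asarray(config.spectrum))
    muts = []
    for k in classes:
        cls = BPS_CLASSES[int(k)]
        pur_ref, pur_alt = _CLASS_REF[cls]
        if config.genome is not None:
            pool = (config._at_positions if cls.startswith("A:T")
                    else config._gc_positions)
            if pool is None or pool.size == 0:
                continue  # genome has no site of this origin pair
            position = int(pool[rng.integers(pool.size)])
            ref = config.genome.base(position)
        else:
            position = int(rng.integers(1, config.genome_length + 1))
            ref = pur_ref if rng.random() < 0.5 else COMPLEMENT[pur_ref]
        alt = pur_alt if ref == pur_ref else COMPLEMENT[pur_alt]
        muts.append(SimMutation(position, ref, alt, False, 0.0, transfer))
    return muts


def _draw_indels(config: SimulationConfig, rng: np.random.Generator,
                 transfer: int, n: int) -> list[SimMutation]:
    muts = []
    for _ in range(n):
        position = int(rng.integers(1, config.genome_length))
        base = (config.genome.base(position) if config.genome is not None
                else BASES[rng.integers(4)])
        nxt = (config.genome.base(position + 1) if config.genome is not None
               else BASES[rng.integers(4)])
        if rng.random() < 0.5:  # single-base deletion, VCF-style anchored
            ref, alt = base + nxt, base
        else:                    # single-base insertion
            ref, alt = base, base + BASES[rng.integers(4)]
        muts.append(SimMutation(position, ref, alt, True, 0.0, transfer))
    return muts


def _assign_effects(muts: list[SimMutation], dfe: DFE,
                    rng: np.random.Generator, coding_index=None) -> list[SimMutation]:
    """Draw a fitness effect per mutation; lethals get s = -inf.

    When a coding index is available, selection acts on function: only
    nonsynonymous substitutions and coding indels draw from the DFE, while
    synonymous and noncoding changes are neutral. Without an annotated
    genome every mutation draws from the DFE.
    """
    out = []
    for m in muts:
        if coding_index is not None:
            intragenic = coding_index.owner_of(m.position) is not None
            affects_protein = intragenic if m.is_indel else (
                intragenic and coding_index.effect_of(m.position, m.alt) == "nonsynonymous")
            if not affects_protein:
                out.append(replace(m, s=0.0))
                continue
        u = rng.random()
        if u < dfe.lethal_fraction:
            s = -math.inf
        elif u < dfe.lethal_fraction + dfe.beneficial_fraction:
            s = rng.exponential(dfe.beneficial_mean_effect) if dfe.beneficial_mean_effect else 0.0
        else:
            s = -rng.exponential(dfe.deleterious_mean_effect) if dfe.deleterious_mean_effect else 0.0
        if m.is_indel and math.isfinite(s):
            s *= dfe.indel_effect_multiplier
        out.append(replace(m, s=s))
    return out


def simulate_transfer(config: SimulationConfig, founder_fitness: float,
                      rng: np.random.Generator, founder_count: int = 1,
                      transfer: int = 0) -> TransferOutcome:
    """Grow one founder for a day: census, divisions, transmitted mutations.

    The final census is lognormal around the treatment median scaled by the
    founder's relative fitness; the transmitted lineage experiences
    log2(n_final/founder_count) divisions. Mutation input is Poisson at
    mu * L * G; lethals are never transmitted, and deleterious mutations are
    thinned with acceptance probability exp(s*G/2) (a mutation arising at a
    uniform time within the day competes for roughly half its generations).
    """
    if founder_fitness <= 0:
        raise ValueError("founder must be viable (fitness > 0)")
    if founder_count < 1:
        raise ValueError("founder_count must be >= 1")
    model = config.n_final
    median = model.median_cells * min(max(founder_fitness, 0.05), 1.5)
    n_final = rng.lognormal(math.log(median), model.sigma_log)
    n_final = max(n_final, 2.0 * founder_count)
    generations = math.log2(n_final / founder_count)

    L = config.genome_length
    n_bps = rng.poisson(config.mu_bps * L * generations)
    n_ind = rng.poisson(config.mu_indel * L * generations)
    proposed = (_draw_bps(config, rng, transfer, n_bps)
                + _draw_indels(config, rng, transfer, n_ind))
    proposed = _assign_effects(proposed, config.dfe, rng,
                               coding_index=config._coding_index)

    transmitted = []
    for m in proposed:
        if not math.isfinite(m.s):
            continue  # lethal: never passes a single-cell bottleneck
        accept = min(1.0, math.exp(m.s * generations / 2.0))
        if m.s >= 0 or rng.random() < accept:
            transmitted.append(m)
    return TransferOutcome(tuple(transmitted), n_final, generations, founder_count)


@dataclass
class ExperimentResult:
    """Simulator output in the schemas the analysis modules read."""

    mutations: pd.DataFrame
    cfu: pd.DataFrame
    curves: pd.DataFrame
    histories: list[LineHistory]
    config: SimulationConfig

    def mutation_records(self) -> list[MutationRecord]:
        from .mutio import frame_to_records
        return frame_to_records(self.mutations)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": out / "mutations.tsv",
            "cfu": out / "cfu.tsv",
            "curves": out / "curves.tsv",
        }
        self.mutations.to_csv(paths["mutations"], sep="\t", index=False)
        self.cfu.to_csv(paths["cfu"], sep="\t", index=False)
        self.curves.to_csv(paths["curves"], sep="\t", index=False,
                           float_format="%.6g")
        return paths


def simulate_experiment(config: SimulationConfig,
                        growth_curves: bool = True) -> ExperimentResult:
    """Run a full MA experiment: all lines, all transfers, all output tables.

    Fully reproducible from ``config.seed``: line ``i`` uses child seed
    stream ``i`` of the root SeedSequence, and its transfers use that
    stream's children in order, so any single line can be re-simulated.
    """
    root = np.random.SeedSequence(config.seed)
    line_seeds = root.spawn(config.lines + 1)  # last child drives growth curves
    prefix = "L" if config.treatment == "liquid" else "P"
    histories: list[LineHistory] = []
    cfu_rows = []

    for i in range(config.lines):
        line_id = f"{prefix}{i + 1:02d}"
        hist = LineHistory(line_id=line_id, treatment=config.treatment)
        transfer_seeds = line_seeds[i].spawn(config.transfers)
        founder_count = 1
        for t in range(config.transfers):
            rng = np.random.default_rng(transfer_seeds[t])
            outcome = simulate_transfer(config, hist.fitness, rng,
                                        founder_count=founder_count,
                                        transfer=t + 1)
            hist.founder_counts.append(outcome.founder_count)
            hist.n_finals.append(outcome.n_final)
            hist.generations.append(outcome.generations)
            hist.mutations.extend(outcome.mutations)
            for m in outcome.mutations:
                hist.fitness *= (1.0 + m.s)
            hist.fitness = max(hist.fitness, 1e-3)
            cfu_rows.append((line_id, t + 1, config.treatment, outcome.n_final))
            if config.treatment == "liquid":
                founder_count = _bottleneck_with_retry(
                    config, outcome.n_final, rng, line_id, t + 1)
            else:
                founder_count = 1  # one colony, one founder cell
        histories.append(hist)

    records = [
        MutationRecord(line_id=h.line_id, position=m.position, ref=m.ref,
                       alt=m.alt, is_indel=m.is_indel)
        for h in histories for m in h.mutations
    ]
    mutations = records_to_frame(records)
    cfu = pd.DataFrame(cfu_rows, columns=["line_id", "day", "treatment", "cfu_per_ml"])

    if growth_curves:
        curve_rng = np.random.default_rng(line_seeds[-1])
        curves = simulate_growth_curves(
            {h.line_id: h.fitness for h in histories}, rng=curve_rng)
    else:
        curves = pd.DataFrame(columns=list(CURVE_COLUMNS))
    return ExperimentResult(mutations=mutations, cfu=cfu, curves=curves,
                            histories=histories, config=config)


def _bottleneck_with_retry(config: SimulationConfig, census: float,
                           rng: np.random.Generator, line_id: str,
                           transfer: int) -> int:
    for _ in range(config.max_transfer_retries):
        try:
            founder, _, _ = simulate_dilution_bottleneck(config.dilution, census, rng)
            return founder
        except FailedTransfer:
            continue
    raise FailedTransfer(
        f"line {line_id}, transfer {transfer}: no turbid well in "
        f"{config.max_transfer_retries} dilution attempts"
    )


def simulate_growth_curves(fitness_by_line: dict[str, float],
                           rng: np.random.Generator,
                           ancestor_id: str = "ANC",
                           lines_per_batch: int = 2, replicates: int = 4,
                           r_ancestor: float = 1.4, od0: float = 0.002,
                           capacity: float = 1.0, noise_sd: float = 0.005,
                           t_end: float = 24.0, dt: float = 0.25,
                           ) -> pd.DataFrame:
    """Logistic OD600 curves for MA lines and same-batch ancestor replicates.

    Mirrors the phenotyping layout: each batch (day) carries
    ``lines_per_batch`` MA lines plus the ancestor, ``replicates`` wells
    each. A line with relative fitness W grows at rate W * r_ancestor
    (per hour); carrying capacity is shared; Gaussian read noise is added
    and clipped at 0.
    """
    times = np.arange(0.0, t_end + dt / 2, dt)
    line_ids = list(fitness_by_line)
    rows = []
    for b in range(0, len(line_ids), lines_per_batch):
        batch = f"day{b // lines_per_batch + 1:02d}"
        samples = [(ancestor_id, 1.0)] + [
            (lid, fitness_by_line[lid]) for lid in line_ids[b:b + lines_per_batch]
        ]
        well = 0
        for sample_id, w in samples:
            r = r_ancestor * max(w, 0.05)
            for _ in range(replicates):
                well += 1
                od = capacity / (1.0 + (capacity / od0 - 1.0) * np.exp(-r * times))
                od = np.clip(od + rng.normal(0.0, noise_sd, size=times.size), 0.0, None)
                well_id = f"{batch}_w{well:02d}"
                rows.extend(
                    (well_id, sample_id, batch, float(t), float(o))
                    for t, o in zip(times, od)
                )
    return pd.DataFrame(rows, columns=list(CURVE_COLUMNS))


def harmonic_mean_popsize(generations: int) -> float:
    """Harmonic-mean census of one doubling series 2^0 .. 2^G.

    Drift in a bottlenecked lineage is governed by this harmonic mean, not
    by the bottleneck size of 1: (G+1) / sum_{t=0..G} 2^-t, which approaches
    (G+1)/2 for large G (about 14 for a 27-generation day).
    """
    if generations < 1:
        raise ValueError("need at least one generation")
    g = int(generations)
    return (g + 1) / sum(2.0 ** -t for t in range(g + 1))
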