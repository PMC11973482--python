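# Methods

## The estimation model

A mutation-accumulation (MA) line is a lineage forced through repeated
single-cell bottlenecks, one per daily transfer. Because every bottleneck
resets the population to (near) one cell, selection has little opportunity
to sort variants, and the accumulation of mutations is approximately a
Poisson process in elapsed cell divisions. The genome-wide rate estimator
is therefore pure arithmetic,

    mu = m / (T · G · L),

with *m* the mean per-line mutation count, *T* the transfers, *G* the
generations per transfer, and *L* the sites at risk. Generations come from
the census: a well or colony grown from one cell to N cells has undergone
log2(N) divisions along any surviving lineage. `mutation_rate_lines`
computes a per-line rate with each line's own realized generation total and
reports the mean and SEM (sd/√n) across lines; `mutation_rate` accepts
experiment-level means when per-line data are unavailable (then no SEM is
emitted). The genome size used in the denominator is an explicit parameter
(default 4.6e6 bp, an E. coli-scale chromosome) because published rates are
sensitive at the ~1% level to which assembly length is assumed.

"Bottlenecked to one cell" does not mean the effective population size is
1: over a day of G doublings the census runs 2^0, 2^1, …, 2^G, and drift is
governed by the harmonic mean (G+1)/Σ2^(−t) = (G+1)/(2−2^(−G)), about 14
for a 27-generation day (`harmonic_mean_popsize`). This is why weak
selection is detectable even in MA designs, and why the simulator models
selection at all.

## Spectrum and per-class rates

Substitutions are strand-collapsed into six classes (a mutation and its
reverse complement are the same double-stranded event), tallied by
`spectrum_counts`. Per-class rates divide each class's count by the site
count of its origin pair — A+T sites for A:T→· classes, G+C sites for
G:C→· classes — times total generations across lines. The 95% CI is the
normal approximation to the Poisson count, count ± 1.96√count, divided by
the same denominator and floored at zero; a zero count yields the
degenerate interval (0, 0). Exact Garwood intervals are available behind
`method="exact"` for small counts, but the normal approximation is the
default because it is the convention in this literature and the counts
involved (hundreds to thousands) make the difference negligible.

## Composition nulls and selection tests

Under neutral placement, mutation counts split between two site categories
in proportion to category sizes. Two nulls are computed from a genome +
CDS annotation by `count_site_classes`:

* **coding : noncoding** — a straight base count (for an E. coli-like
  genome with 3.95e6 coding and 6.88e5 noncoding sites, 5.74 : 1);
* **effectively nonsynonymous : synonymous** — Nei–Gojobori site counting:
  each coding position contributes 1/3 of a site per possible substitution,
  classified by translating the owning codon before and after the change.
  Substitutions that create or destroy a stop codon count as nonsynonymous;
  stop-to-stop changes are synonymous. Start codons get no special
  treatment. The genetic code defaults to NCBI table 11 and is
  configurable.

Positions covered by overlapping CDS features are counted once, owned by
the first gene in annotation order, with a warning listing the conflicts;
a CDS with internal stop codons warns but still counts. Coordinates are
1-based inclusive throughout (GFF3 convention).

`composition_ratio_test` is the 1-df χ² goodness-of-fit of an observed
two-category split against the site proportion; `ns_s_test` specializes it
to the effective-site null. P-values are reported uncorrected, and the
expected-cell-below-1 regime triggers an approximation-quality warning.
Indels use the coding/noncoding null without length weighting; coding
indels are labeled "disruptive" (nonsynonymous-equivalent) in annotation.

Fitness consequences are summarized by `fitness_cost_per_mutation`: each
line contributes (W − 1)/burden with W its ancestor-normalized fitness and
burden its total substitution + indel count; zero-burden lines are excluded
with a warning. Treatment contrasts use Welch's t (variance equality is
not assumed) or the Mann–Whitney U test — exact enumeration up to n = 8
per group without ties, continuity-corrected normal approximation
otherwise; two identical constant samples return p = 1 with a warning
rather than a 0/0.

## The forward simulator

`simulate_experiment` emulates both MA designs end to end and emits
exactly the tables the analysis reads (mutation TSV, per-line per-day CFU
TSV, long-format OD600 TSV), so estimator validation is a closed loop.

**Growth.** Each transfer draws the final census from a lognormal
parameterized by median and CV. Defaults: liquid wells reach a median of
1e9 cells (29.9 doublings of a 1 mL culture) with CV 0.12; plate colonies
a median of 1.25e8 cells (26.9 doublings) with CV 0.5. The medians encode
the observation that deep-well liquid cultures support ~10% more divisions
per day than colonies; the CV gap encodes colony-crowding variability that
liquid culture lacks. A lognormal was chosen because the census is a
positive multiplicative quantity; only median and CV are asserted by the
emulated design, not the family.

**Mutation input.** Mutations per transfer are Poisson(μ·L·G) with G the
lineage's realized divisions. Defaults μ_bps = 2.8e-8 and
μ_indel = 6.5e-9 per site per generation, with the transition-skewed
mismatch-repair-deficient spectrum (A:T→G:C frequency 0.81) as the default
class distribution. Positions are uniform; when a real/synthetic genome is
attached, each substitution is placed on a site of its origin pair
(A:T→· classes on A/T sites), so ref/alt bases are consistent with the
sequence. Indels are a single class (no length spectrum), VCF-style
anchored, uniform in position.

**Selection.** Each mutation draws a fitness effect: lethal with
probability 0.005, beneficial with probability 0.001 (exponential, mean
1e-3), otherwise deleterious (exponential, mean 1e-3); indel effects are
scaled 3×. These defaults were chosen once to be consistent with a
per-mutation fitness cost on the order of −1e-3 and stronger purifying
pressure on indels; a strictly neutral DFE (`DFE.neutral()`) is used for
estimator-calibration runs. When an annotated genome is attached,
selection acts on function: only nonsynonymous substitutions and coding
indels draw from the DFE, synonymous and noncoding changes are neutral —
this is what makes purifying selection depress the intragenic mutation
share below the composition null, and positive selection inflate it.
Rather than agent-based simulation of 1e9 cells, transmission through the
bottleneck is thinned with acceptance probability min(1, exp(s·G/2)): a
mutation arising at a uniform time within the day competes for on average
half its generations (a branching-process approximation). Lethals are
never transmitted and do not perturb the census (the surviving lineage is
by construction one that did not inherit them).

**Bottlenecks.** The liquid design dilutes the day's culture across rows
of wells with strictly decreasing expected cells per well; each well's
founder count is Poisson, a well is turbid if it holds at least the
turbidity threshold (default 1 viable cell), and the transfer continues
from the leftmost turbid well of the most dilute turbid row. The default
rows (λ = 2.0, 0.5, 0.2; 8 wells each) are back-calculated from the
emulated protocol volumes: 20 µL of a 10⁻⁷ dilution and 50 µL / 20 µL of a
10⁻⁸ dilution of a ~1e9 CFU/mL overnight culture; λ scales linearly with
the source census. A day on which every well stays clear is retried with
fresh random draws up to 10 times, then raised as a failed transfer with
line/day context — with the default three-row design the failure
probability per day is e^(−21.6) ≈ 4e-10, so the retry bound exists only to prevent
hangs under pathological configurations. The alternative 1:2
serial-dilution strategy is expressible as a custom `DilutionDesign` row
list. The plate design picks one colony — always a single founder cell,
modeled as a uniformly random colony (any size bias of human colony
picking is not asserted).

When the chosen well was founded by f > 1 cells, the transmitted lineage
experiences log2(N/f) divisions while the CFU-based estimator still uses
log2(N), exactly as a census-based analysis would; with the default design
this reproduces the real protocol's small (<0.5%) downward bias in the
estimated rate rather than idealising it away.

**Randomness.** One root seed; line *i* consumes child stream *i* of the
root `SeedSequence` and its transfers consume that stream's children in
order, so any single line or transfer can be re-simulated in isolation.
All outputs are byte-identical across runs at a fixed seed.

**Growth curves.** Phenotyping batches mirror the plate-reader layout: per
batch, two MA lines plus the ancestor, four replicate wells each, 24 h of
quarter-hourly logistic OD600 readings (r_ancestor = 1.4 h⁻¹, carrying
capacity 1.0 OD, initial OD 0.002 ≈ a 1:100 back-dilution, Gaussian read
noise sd 0.005, clipped at 0). A line with relative fitness W grows at
rate W·r. The generator emulates smooth batch-consistent curves; it does
not emulate evaporation outliers, lag-phase variation, diauxie, or
between-day reader drift, so passing recovery tests demonstrate estimator
correctness on clean curves, not robustness to those artifacts.

## Growth metrics

`max_growth_slope` is the maximum over 5-point sliding windows (windows
fully inside 2–10 h) of the least-squares OD-vs-time slope; "slope
averaged across a window" is interpreted as the OLS slope because it is
the stabler estimator, with the mean-of-finite-differences variant behind
`method="diff"`. `carrying_capacity` averages the 5 readings nearest 12 h,
ties broken toward the earlier reading (the centered-window choice among
the plausible readings of "average around 12 h"). No wells are discarded
or blank-subtracted by default. `relative_fitness` divides each line's
metric by the mean ancestor metric of its own batch, so day effects cancel;
a batch without an ancestor replicate is an error rather than a silent
global normalization.

## Numerical and I/O conventions

* TSV mutation schema: `line_id, position, ref, alt, type(BPS|INS|DEL)`
  plus optional `bps_class, genic, effect`; header mandatory; malformed
  rows reported with line numbers. Minimal VCF 4.x is accepted on a single
  contig, multi-allelic records split; multi-nucleotide substitutions are
  split into component single-base records with a warning.
* A mutation table validated against a genome requires genome base ==
  ref at every position (first ref base for indels); mismatches name the
  offending record.
* Spectra with zero substitutions flag frequencies as undefined rather
  than emitting NaNs.
* Rates below machine-relevant magnitudes are kept at full precision
  internally; rounding happens only in report rendering.
* Simulation rate parameters are validated to [0, 1e-3) per site per
  generation — zero is allowed (it is the natural "off" switch and the
  degenerate case of the Poisson input), and 1e-3 is far above any
  biologically plausible per-site rate.

## Problem sizes and what the tests show

The test suite runs at desk scale by design: exhaustive substitution
oracles on synthetic genomes up to ~3 kb, 1e5–2e5-well occupancy checks,
1e5-replicate bottleneck-distribution comparisons, 2e5–1e6-draw multinomial
oracles, and 50-replicate estimator-recovery runs of the full 16-line ×
20-transfer experiment (a few seconds each; the mutation process is
simulated at the event level, not the cell level, so problem size is set
by mutation counts, not census). These sizes give Monte-Carlo standard
errors comfortably below the tolerances asserted. Passing them shows the
estimators are unbiased on data satisfying the generator's assumptions
(Poisson input, lognormal census, independent lines); they cannot show
robustness to upstream variant-calling artifacts, shared ancestry from
cross-contamination, or context-dependent mutation processes, which the
generator deliberately does not emulate.

## Known limitations

* Site counting is codon-exact but not codon-usage- or
  transition/transversion-weighted; non-CDS features (rRNA, tRNA) are not
  annotated.
* The per-class CI is the conventional normal approximation; for counts
  below ~10 prefer `method="exact"`.
* Selection within a transfer is a thinning approximation, not an
  agent-based competition; it represents the direction and magnitude of
  selection well but not clonal-interference dynamics.
* The spectrum's class probabilities are global, not conditioned on local
  sequence context.
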