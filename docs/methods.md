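# Methods

## Measurement model

A sample's diploid DEFA1A3 copy number N is treated as an unknown integer
between `n_min = 2` and `n_max = 16`. Five assays measure N independently.

**PRT assays.** A paralogue ratio test co-amplifies a copy-variable target
and a fixed two-copy reference locus; after calibration its output *m* is an
unrounded estimate of N. Empirically the spread of PRT measurements scales
with copy number: the standard deviation of the *normalised* measurement
*m*/N is approximately constant across copy-number classes, at 0.114
(MLT1A0) and 0.12 (DEFA4). The likelihood of *m* under candidate N is
therefore the Normal(N, (σ_rel·N)²) density, evaluated with its 1/(σ_rel·N)
prefactor — the width varies across candidates, so the prefactor genuinely
discriminates (it slightly favours smaller N, correctly, since a wider
Gaussian spends its mass over more ground).

The MLT1A0 assay targets a sequence present only in full 19 kb repeats, not
in the once-per-haplotype partial repeat, so it counts two copies fewer per
diploid than the other assays. By convention its calibration maps raw
ratios directly to the *total* repeat count, which is why the calibration
intercept is retained rather than forced through the origin.

**Allelic-ratio assays.** Each ratio assay quantifies the peak-area ratio
between two variant classes carried on different repeats: indel5
(deleted : undeleted), DefHae3 (DEFA1 : DEFA3) and 7bpdup
(unduplicated : duplicated). Under copy number N the classes split as an
integer composition (a, b), a + b = N. Both peaks being measured implies
both classes are present, so a, b ≥ 1; single-peak observations are recorded
as missing. The expected observed ratio of composition a:b is k·a/b with a
per-assay calibration constant k (default 1). The likelihood at N is the
maximum over compositions of a Gaussian kernel on the comparison metric
between observed and expected ratio.

The default metric is log(r / expected) with σ_ratio = 0.15: peak-area
noise is multiplicative, and the log metric makes scoring symmetric under
reversal of an assay's orientation (reciprocal ratios give mirrored
interpretations, e.g. 2:5 versus 5:2). A linear metric (r − expected) is
available via `ErrorModel(ratio_metric="linear")`. Scoring by the *best*
composition matches the convention of reporting a single best integer
interpretation per assay; `composition_mode="sum"` marginalises over
compositions instead.

**Combination and calling.** Each per-assay row is rescaled to a maximum of
exactly 1 over the full copy-number range; a missing assay contributes an
all-ones row. Rows are combined by element-wise multiplication and
rescaled again; relative likelihoods below 10⁻³⁰⁸ (double-precision
underflow) are rounded to 0. The MLCN is the argmax (exact ties break to
the smaller N with a flag); the minimum ratio MR = best / second-best
combined value. Because every row is only ever used relative to its own
maximum, the call is invariant under positive rescaling of any single assay
row — a property-tested invariant.

**QC and anomaly flags.** A sample is included when it has at least two
present measurements, at least one a PRT. After calling, any assay whose
relative likelihood at the MLCN falls below 5 × 10⁻⁴ (~3.9 σ) is flagged:
it contradicts the assumption that one underlying copy number explains all
measured sequence elements. At this threshold a residual false-flag rate
of order 10⁻⁴ per assay is expected and observed in simulation. A
strongly discordant assay can also drag the combined call away from the
truth rather than being flagged at it; flag rates are therefore best read
conditionally on the call (see the simulation test).

## Calibration and error-model estimation

`fit_prt_calibration` maps raw PRT ratios to copy numbers by ordinary least
squares against reference samples of known integer copy number (at least
two distinct values required), with copies as the response. Rounding is
never applied inside calibration. `estimate_error_model` re-derives σ_rel
as the SD of normalised measurements over a called cohort and tallies
|z| > 2 outliers against the Gaussian expectation, the diagnostic under
which the MLT1A0 assay shows a known low-side excess.

## Population genetics

`hwe_expected` convolves a haplotype copy-number frequency table with
itself: under Hardy-Weinberg equilibrium P(N) = Σ_{h1+h2=N} f(h1)·f(h2),
with optional binning into open-ended classes ("≤3", "12+").
`compare_distributions` performs a Pearson chi-square: goodness-of-fit
(expected counts n·p, df = classes − 1, optional seeded Monte-Carlo null
for small expected counts) when the expected side is a probability vector,
and a two-sample contingency chi-square when both sides are observed
cohorts — the appropriate choice for cross-study comparisons, where both
distributions are estimates. Classes with zero expected probability are
merged into a neighbour and reported. `snp_cnv_association` reports r²
from regressing copy number on allele dose (0/1/2) plus a genotype ×
copy-number-class contingency chi-square, with per-genotype histograms for
plotting; the method is recorded in the output metadata since different
association constructions give very different P values.

## Pedigree segregation

Each person's diploid totals (copies, DEFA3, indel5-deleted,
7bp-duplicated counts; any may be missing) are the sum of two haplotypes.
`enumerate_haplotype_solutions` exhaustively splits each founder's totals
into two haplotypes (copy numbers searched in 0…`max_hap_copies`, default
5, reflecting that most repeat alleles carry 1–5 copies and zero-copy
haplotypes are possible), transmits one haplotype from each parent to each
offspring, and keeps assignments reproducing every observed total exactly —
no recombination or de-novo mutation is absorbed; inconsistencies raise an
error naming the first unsatisfiable member. Solutions differing only by
within-parent relabelling are merged; multiple surviving solutions set an
ambiguity flag. Missing totals simply drop their constraint.

Two structural facts, confirmed against a generate-and-test oracle, shape
how results should be used. First, copies-plus-one-variant data often
under-determines even a two-child nuclear family; all four measured
dimensions usually pin the split down. Second, grandparental splits in a
three-generation family are constrained by only one offspring and are
systematically ambiguous from these data alone — resolving them requires
external phase information, which is out of scope — so haplotype frequency
tables are built from parental (nuclear-family) resolutions via
`haplotype_frequency_table`, counting founder haplotypes of uniquely
resolved families.

The search interleaves constraint checks with founder enumeration (a
parent's totals prune the paternal grandparents' splits before the
maternal side is enumerated), keeping exhaustive search tractable for
realistic three-generation families.

## Simulator

`simulate_cohort` draws haplotype pairs i.i.d. from a frequency table
(Hardy-Weinberg), `simulate_panel` adds measurement noise: PRT values
Gaussian with SD σ_rel·N around the true total, ratios log-normal (or
additive-normal under the linear metric) around k·a/b of the true
composition, with structural missingness when a variant class is absent
and optional per-assay random missingness. The default haplotype table
(support 1–7 copies) was fitted once by least squares so that its HWE
convolution approximates the observed European diploid distribution
bundled in `reference_data`; variant compositions follow the worked
examples (0–2 DEFA3 genes per haplotype, about half of repeats
indel5-deleted, a majority 7bp-duplicated).

The simulator reproduces the statistical structure the caller assumes —
which means recovery experiments measure the *Bayes-optimal* error of the
calling rule, not assay artefacts. At the default noise levels the
raw-measurement SD at N = 7 is ≈ 0.8 copies, and per-copy-number
concordance falls from ~1.0 at N ≤ 4 to ~0.75 at N = 7 and ~0.65 at N = 8
(~77 % aggregated over copy numbers ≤ 8 under the default mix); this is an
information floor of the measurement model itself, consistent with the
broad spread of real-data MR values, and no decision rule can beat it under
these conditions. What passing recovery tests do show: correct
implementation of the likelihoods, monotone degradation with noise and copy
number, and unbiased σ recovery. What they do not show: real assays'
departures from Gaussianity (the MLT1A0 low-z outlier excess), batch
effects, or calibration drift — none of which are simulated.

## Numerical choices and limitations

* Relative likelihoods are normalised to max 1 per row and per combined
  row over the full 2–16 range, never over a display window.
* Values below 10⁻³⁰⁸ become exactly 0; a row that underflows everywhere
  degrades to all-ones rather than NaN.
* Ties at the argmax break toward the smaller copy number, flagged.
* Ratio calibration constants k and σ_ratio are configuration with
  documented defaults (k = 1, σ = 0.15); published per-assay worked rows
  reflect assay-specific calibration not reproduced here, so per-assay rows
  are compared only through their combination.
* The bundled worked-example rows are printed to 3 significant figures;
  recombined entries are ratios of five-factor products, so agreement is
  limited to ~5 % worst-case on individual entries (MR agrees to ~1 %).
* MR is reported as computed over 2–16; copy numbers outside this range
  are never considered.
* `PopulationDistribution.median()` represents open-ended bins by their
  closed edge, adequate while the bins hold little mass.
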