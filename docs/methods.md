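# Methods

## The 5-FUrd-per-ribosome estimator

A ribosome's rRNA complement is a fixed molecular formula: one copy each
of the 18S, 28S, 5.8S and 5S species, hence exact per-ribosome counts
N_A, N_C, N_G, N_U obtained by tallying the sequences. After digestion
of purified rRNA to nucleosides, the molar concentration of reference
nucleoside X ∈ {A, C, G} in the digest is proportional to the number of
ribosome-equivalents, [X] = ρ·N_X for ribosome concentration ρ, while
[5-FUrd] = ρ·f with f the mean number of incorporated 5-FUrd molecules
per ribosome. Eliminating ρ gives the single-reference estimator

    f̂_X = ([5-FUrd]/[X]) · N_X,

computed for each of A, C and G and summarised by mean and sample
standard deviation (ddof = 1; zero for a single reference). The spread
across references is a purity/consistency diagnostic: it vanishes
exactly when the measured concentrations are proportional to the
composition, and grows when non-ribosomal RNA contaminates the digest or
one channel drifts. A pooled estimator
[5-FUrd]/([A]+[C]+[G])·(N_A+N_C+N_G) is provided as an option; on
internally consistent data the two coincide. Uridine is excluded as a
reference because 5-FUrd substitutes for uridine, making [U] itself a
function of treatment.

The estimator is exactly invariant to rescaling all concentrations by a
common factor (units cancel), strictly increasing in [5-FUrd], and zero
iff [5-FUrd] is zero. Estimates with [5-FUrd] below a configurable limit
of detection are flagged "not detected" rather than reported as zero,
since absence of signal and measured zero are different statements.

Under the package's measurement model (independent lognormal
multiplicative noise per channel at coefficient of variation c), the
ratio [5-FUrd]/[X] is biased upward by roughly a factor exp(σ²) − with
σ² = ln(1+c²) — about +0.25% at c = 5%, far below the assay's
replicate scatter; the acceptance check quantifies the realised bias at
planted truths of 1, 5 and 14 molecules/ribosome and requires it below
5%.

## Calibration

Instrument response is the analyte peak area divided by the
stable-isotope internal-standard area; a per-analyte ordinary
least-squares line of response vs known concentration (fitted intercept)
maps sample responses back to concentrations, clipped at zero, with
values outside the standards' span flagged as extrapolated. A fit uses
at least three standards at two or more distinct levels and warns when
r² < 0.99. These are the standard mechanics of isotope-normalised
nucleoside assays; this package does not model chromatogram processing
or peak integration, which sit upstream.

## Translation efficiency

TE for a gene in a condition is the polysomal over cytoplasmic mRNA
quantity. Ct values convert to relative quantities as efficiency^(−Ct)
(default efficiency 2.0 — ideal doubling — configurable per primer
pair); replicates aggregate by the geometric mean of quantities,
equivalent to the arithmetic mean of Ct, because qPCR measures on a log
scale. TE is reported raw and normalised per gene to the mean TE of the
control (untreated) condition, whose normalised value is 1 by
construction. TE is invariant to any per-sample rescaling of quantities.

## Reporter assays and growth

The dual-luciferase ratio is (Fluc − blank_F)/(Rluc − blank_R) per well,
using the mean of designated blank wells per plate (zero when none are
marked); a Renilla signal at or below its blank is an error, not a
ratio. Bicistronic IRES activity and monocistronic cap-dependent
activity share this arithmetic — interpretation lives in experiment
metadata. Fold-changes divide by the arithmetic mean of the control
condition, so the control's mean fold-change is exactly 1 and the
operation is idempotent; the same operation expresses MTS viability as
percent of untreated.

Growth rate is the OLS slope of cell index vs time restricted to a
window (e.g. 72 h), taken on the raw index as the closest literal
reading of a rate "as the slope"; a log-index option gives an
exponential-phase rate instead. The slope is invariant to additive index
offsets and scales linearly with multiplicative rescaling.

## Differential-translation post-processing

The negative-binomial model fit (DESeq2-style Wald test) is consumed,
not reimplemented: classification starts from tables of gene id, log2
fold change and (adjusted) p-value. Count matrices are filtered at a
minimum of 1 count per million in every biological sample by default
("in at least k samples" available); library sizes are column sums
unless overridden and are carried through the filter unchanged.
Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest` behind the package's own surface, and is
verified in the tests against an independently written two-pass step-up.

A gene is translationally up when log2FC > 1 and padj < 0.05, down when
log2FC < −1 and padj < 0.05 ("more than twofold" is a strict
inequality, so a gene at exactly twofold is unchanged; both thresholds
are configurable). The three classes partition the input genes. Summaries
report n_up, n_down, n_total and the upregulated fraction rounded to the
nearest integer percent — undefined (not zero) when no gene is altered —
plus only-A/both/only-B overlaps of the up and down sets when two doses
are compared. The fraction of all analysed mRNAs that is altered is
reported only when the classification covers the full filtered gene
universe, since the denominator is otherwise unknown.

## Synthetic data

Each generator draws from a `numpy.random.default_rng(seed)` created
per call (no global state; a fixed seed gives byte-identical output) and
is invertible by its paired estimator — exactly at zero noise, within
pre-validated tolerance at the stated noise:

- **Nucleoside concentrations**: expected [X] = ρ·N_X and
  [5-FUrd] = ρ·f, times unit-mean lognormal noise at a given CV
  (instrument responses are positive with roughly proportional error).
  Default CV 2% (replicate-level assay precision), 5% in the recovery
  study.
- **Calibration standards**: response = slope·c + intercept + Gaussian
  noise, internal-standard area at a nominal constant.
- **qPCR**: cytoplasmic Ct around a nominal baseline of 22 cycles,
  polysomal Ct offset by −log_eff(TE), additive Gaussian Ct noise
  (default sd 0.1 cycles, typical technical-replicate scatter).
- **Differential-translation tables**: planted up/down genes at
  log2FC = ±2 with padj drawn below 0.05, null genes with log2FC noise
  (sd 0.3) and padj ≥ 0.05; raw p-values derived by inverting the
  step-up within ranks so p ≤ padj and ranks agree. Emitting padj
  directly reflects that the count-model fit is out of scope; a
  negative-binomial count-matrix generator (lognormal gene means,
  dispersion 0.1, ~10⁶ library size) exercises the CPM filter.
- **Growth curves**: index = intercept + slope·t + Gaussian noise.
- **Synthetic rRNA set**: random GC-biased sequences at the human rRNA
  lengths (18S 1869, 28S 5070, 5.8S 157, 5S 121 nt). These are labelled
  synthetic stand-ins — realistic in length and base skew, not in
  sequence; any real rRNA FASTA can replace them.

What passing tests show — and don't. The generators realise the
estimators' own measurement models, so round-trip recovery demonstrates
correctness of the arithmetic and robustness at realistic noise levels;
it does not probe violations real data can exhibit (non-ribosomal RNA
contamination, calibration nonlinearity at range edges, qPCR efficiency
drift, correlated errors across analytes, incomplete ribosome turnover
during treatment).

## Numerical choices and degenerate inputs

Back-calculated concentrations are clipped at zero; calibration requires
≥ 2 distinct levels (else "degenerate design"); compositions reject
sequences whose IUPAC-ambiguous fraction exceeds 1% and track smaller
amounts separately, warning; empty FASTA files, empty records, missing
fractions, duplicate qPCR replicates, non-positive library sizes, and
p-values outside [0,1] all raise data errors rather than propagate.
Tabular outputs are written at six significant digits for reproducible
diffs; pipeline configs are validated completely (paths, parameter
ranges) before any stage runs, so invalid configs never leave partial
outputs.

## Problem sizes

The test suite and acceptance script run the recovery study at 1000
simulated triplicate experiments per planted truth, the FDR oracle
comparison on 1000 random p-value vectors, CPM-filter equivalence on
300–400-gene negative-binomial matrices, and classification on
10⁴-gene tables — sizes chosen to estimate the relevant biases and
agreement rates tightly while keeping a full run in seconds on one CPU.

## Known limitations

- The composition treats modified residues as their parent base; FASTA
  cannot represent them, and 5-FUrd occupancy itself is what is being
  estimated, not annotated.
- The per-reference sd summarises consistency across references, not
  propagated instrument error; it matches the reporting granularity of
  replicate-level mean ± sd.
- The pipeline starts at integrated peak areas and at DE-result tables;
  raw spectra and read-level processing are out of scope.
- Which rRNA species enter the "per ribosome" denominator for
  whole-ribosome preparations is an experimental choice; both the
  four-species default and restricted sets (e.g. gel-purified 18S+28S)
  are supported rather than fixed.
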