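# Methods

`mitosignal` implements the analysis chain behind a peripheral-blood mtDNA
copy-number biomarker of cerebral mitochondrial dysfunction after traumatic
brain injury: mtDNA-specific assay design, relative quantification by
comparative Ct, high-resolution respirometry analysis, and the paired
statistics linking the biomarker to brain bioenergetics. This note documents
the models, the defaults and why, what the synthetic generators do and do not
emulate, and the numerical choices.

## 1. mtDNA-unique region screen and primer design

**Problem.** Nuclear genomes carry partially diverged copies of mitochondrial
sequence (NUMTs). A qPCR assay meant to count mtDNA molecules must amplify
regions with no near-identical nuclear copy, otherwise the nuclear signal
inflates the ratio.

**Screen.** The circular mitochondrial sequence is tiled into windows
(default 100 bp every 10 bp, wrapping the origin). Each window's best
ungapped identity against the nuclear contigs (both strands) is found by
exact 15-mer seeding: every shared 15-mer defines a diagonal, and the full
window is compared at that diagonal (out-of-range positions count as
mismatches). Maximal runs of windows below the identity threshold (default
0.80) become *unique regions*; runs that wrap the origin are split at
position 0 so that emitted coordinates are plain 0-based half-open intervals.
Seeding is exact for the screen's purpose: a 100 bp window at >= 80% identity
with fewer than ~7 substitutions in any aligned stretch always shares a
15-mer with its source, and the planted-NUMT regime the screen exists for
(few percent divergence) is far inside that bound. Windows sharing no 15-mer
report identity 0 rather than their true ~0.4 random-background identity;
only the thresholded decision feeds region construction. Equality with a
literal all-offsets scan is enforced in the tests on multi-kilobase
instances.

With an empty nuclear genome the whole mitochondrial genome is one unique
region — documented behaviour, not an error.

**Primer/probe design.** Within a region, primer candidates are all windows
of 25–30 nt with GC in [0.30, 0.70] and nearest-neighbor Tm in [50, 65] °C
(target 58 °C). The 25–30 nt length floor is the assay family's specificity
constraint and is asserted on every design run. Melting temperatures use the
unified nearest-neighbor parameter set (SantaLucia 1998 via Biopython's
`Tm_NN`, 50 mM Na+, 25 nM strands, SantaLucia entropic salt correction); the
printed reference primers evaluate to ≈54 °C under these conditions, which
motivated the Tm window. A pair is a forward window plus the reverse
complement of a downstream window with amplicon length 60–200 bp and room for
an 18–25 nt hydrolysis probe strictly between the primers (probe Tm chosen
closest to the primer mean; no +10 °C rule is imposed — the reference probes
are short and cooler than their primers). Pairs are ranked by

    |Tm_f − Tm_r| + |Tm_f − 58| + |Tm_r − 58| + |GC_f − 0.5| + |GC_r − 0.5|

with deterministic tie-breaking on (forward start, reverse end). For very
long regions, candidates are truncated to the best 800 per side by individual
score before pairing — a beam limit that keeps design O(candidates²) while
preserving determinism. An empty result is valid (e.g. homopolymeric
regions).

**Specificity check.** Each finished oligo is slid across every nuclear
offset on both strands; the report carries the best full-length identity and
whether any site combines an exact match of the 3'-terminal 5 bases with
>= 90% overall identity — the geometry most likely to extend off-target.

## 2. Relative quantification (comparative Ct)

Triplicates are collapsed to mean and sample SD; triples with SD above 0.5
cycles are flagged, never dropped (auditability). For each sample,
dCt = Ct_target − Ct_16S; for each gene, ddCt subtracts the calibrator's dCt,
and RQ = 2^−ddCt. Amplification efficiency is fixed at 2 (an `efficiency`
hook exists but all reported statistics assume perfect doubling). The
calibrator is either an explicit sample or, by default, the per-gene mean dCt
of all pre-injury samples, which centres pre-injury RQ near 1 — consistent
with published pre-injury group means in the 0.7–1.2 range.

Pooling returns mean, SEM (sample SD with n−1 over √n; defined as 0 for a
single value) and n over all gene × animal values of a group. The published
pooled aggregates are reproduced from the packaged per-gene group means: the
pre-injury pool weights the nine per-gene means by their group sizes
(4 + 4 + 5 animals × 3 genes = 39 values → 0.8403 ≈ 0.84); the post-injury
pools average the three per-gene means of each group (2.0667 ≈ 2.07 for the
diffuse 6 h group, 1.3500 for the focal 25 h group). The same arithmetic on
the diffuse 25 h column gives 2.36 against a printed 2.37 — a rounding-level
discrepancy in the source tables, reported nowhere as a check. One printed
cell ("072±0.21") is read as 0.72.

RQ is invariant under adding a constant to all Cts of a sample (dCt removes
sample-level loading shifts), and the calibrator's RQ is identically 1 —
both are property-tested.

## 3. Respirometry (SUIT trace analysis)

Units: O2 in µM, time in s, tissue concentration in mg ml⁻¹, flux in
pmol O2 s⁻¹ mg⁻¹ with consumption positive; flux J at concentration c gives
an O2 slope of −J·c/1000 µM/s. Calibration is two-point linear (air
saturation × medium solubility factor, default 0.92 relative to pure water;
zero); the air-saturation concentration is a required configuration value
because it depends on temperature and pressure.

The flux series is the negative Savitzky–Golay derivative (local quadratic,
default 21 s window) scaled by 1000/c; a plain finite-difference mode exists
for oracle checks. Negative flux (reoxygenation) is reported, not clipped.
Phases are the intervals between titration events, each starting after a
60 s equilibration exclusion (default); samples before the first event form a
"baseline" phase; a phase fully consumed by equilibration is reported empty
with a warning.

**Plateau extraction.** Within a phase, the window (default 300 s) minimising
the rolling SD of the flux series is selected as the most stable plateau; the
reported flux is the least-squares O2 slope over that window. On noise-free
data this equals the mean flux; under white µM-level noise the regression
slope is several-fold less variable than averaging the smoothed derivative,
whose error scales as T^−3/2 in the window length T. This is also why the
default window is 300 s rather than something shorter: at a realistic
0.2–0.5 µM noise SD, windows of tens of seconds cannot resolve LEAK-scale
fluxes (~14 pmol s⁻¹ mg⁻¹) to a few percent, while 300 s windows sit
comfortably inside real SUIT phase lengths (minutes per titration step). The
respiratory control ratio is OXPHOS_CI+CII / LEAK_CI+CII; a non-positive
LEAK leaves the RCR explicitly undefined rather than producing a misleading
number.

Verified recovery properties (tests): median |error| < 2% over a grid of
fluxes 10–150 and noise 0–0.5 µM; per-phase error < 2% on a two-phase trace
at 0.5 µM noise; RCR within 3% of the generator truth ratio; exact scaling
(doubling concentration halves flux) and time-shift invariance.

## 4. Cohort statistics

* **Wilcoxon signed-rank** (pre vs post, per gene and pooled): exact mode
  computes the full null of W+ over all 2^m sign assignments of the ranked
  |differences| via convolution (identical to literal enumeration, tested
  against it at n ≤ 12); midranks handle ties. Zero differences follow the
  Pratt convention by default (ranked, then their contribution dropped), with
  a drop-zeros option. The normal approximation uses the exact mean ΣR/2 and
  variance ΣR²/4 of the realised rank multiset with a 0.5 continuity
  correction. All-zero differences give p = 1 with a warning.
* **Mann–Whitney U** (between groups): exact null by subset-sum DP without
  ties, literal combination enumeration with midranks when ties are present
  (up to ~2·10⁵ splits), tie-corrected normal approximation beyond. The
  statistic is U of the first sample.
* Two-sided p-values double the smaller tail and cap at 1, matching common
  software; both tests are invariant under monotone data transforms
  (property-tested).
* **RM-ANOVA across genes**: one-way within-subject F = MS_gene / MS_(gene ×
  animal), df (g−1, (g−1)(a−1)); missing cells are an error (no imputation);
  no sphericity correction by default, matching plain RM-ANOVA reporting;
  cross-checked against statsmodels' AnovaRM.
* **Association**: per injury group, Pearson r between the gene-averaged
  post-minus-pre RQ and the sham-referenced respiratory deficit
  (sham mean − post-injury respiration, computed, never stored). The sign
  convention is fixed by the record type: positive r means bigger peripheral
  mtDNA increases accompany bigger cerebral deficits. The respiration
  endpoint (OXPHOS or RCR) must be consistent within a run. p-values come
  from the t transform of r (checked against a 10⁵-resample permutation
  oracle); slope/intercept are reported for plotting.
* No multiple-testing correction is applied anywhere; reports carry raw
  p-values with that caveat.

## 5. Synthetic data: what it emulates, and what it does not

All generators are pure functions of (seed, parameters); determinism is
tested byte-for-byte.

* **Genomes** — uniform-composition random sequence; NUMTs are copies of
  random mito intervals (either strand) with exactly round(length ×
  divergence) substituted positions, overwriting non-overlapping nuclear
  loci; infeasible packing raises. No indels, no realistic porcine
  composition, no repeat structure: this keeps the brute-force oracle exact.
  Consequently the screen's false-positive behaviour on low-complexity real
  chromatin is untested here.
* **Ct tables** — per animal × gene, a latent RQ is drawn log2-normally
  around the group × timepoint mean (ddCt is linear in log2 space, matching
  the assay's error structure), converted to a dCt against a fixed 16S level,
  and expanded into triplicates with Gaussian cycle noise (default 0.15
  cycles between replicates, 0.25 log2 units between animals — conventions,
  since source variances at Ct level are unpublished). Defaults for group
  means use the published pooled fold changes. No plate effects, no
  efficiency drift, no non-detects.
* **Oxygraph traces** — piecewise-linear O2 with the exact flux/slope unit
  arithmetic, a decaying positive spike (2 µM, τ = 10 s) at each titration so
  the equilibration exclusion is actually exercised, and white Gaussian noise
  (default 0.2 µM at 1 Hz). Default plan: baseline 400 s at 15, OXPHOS 600 s
  at 82.6, LEAK 600 s at 14 pmol s⁻¹ mg⁻¹ from ~190 µM — desk-scale values
  consistent with the published sham magnitudes. Real traces have correlated
  sensor noise, drifting plateaus and reoxygenations; passing the recovery
  tests shows the estimator chain is correct and noise-efficient, not that it
  is robust to every instrumental artifact.
* **Cohorts** — bivariate normal (delta-RQ, deficit) pairs with prescribed
  correlation via the Cholesky construction, so true_r = 1 yields exactly
  collinear data. Default scales: delta-RQ 1.2 ± 0.5, deficit 20 ± 8
  pmol s⁻¹ mg⁻¹ around the sham mean.

## 6. Problem sizes

Tests and the acceptance script run the screen-vs-oracle comparison at
6.5 kb mito / 40 kb nuclear (the brute-force scan is the binding cost), flux
recovery on 600 s single-phase traces at 1 Hz, the association recovery at
n = 200 animals over hundreds of seeds, and the Wilcoxon size estimate over
5,000–10,000 null simulations at n = 12 (the exact null for a rank multiset
is cached, making each simulation a table lookup). These sizes were chosen as
the smallest at which the target precisions are statistically resolvable.

## 7. Known limitations

* Ungapped screening only; an indel inside a NUMT shifts the diagonal and
  splits the match (v1 scope; the generator plants substitution-only NUMTs).
* Perfect-doubling ddCt; no standard curves or per-well efficiency.
* The plateau extractor assumes uniform sampling for the Savitzky–Golay path
  and one stable plateau per phase; oscillating phases will still return the
  most stable window.
* `reproduce-paper` operates on printed group means, so it verifies pooling
  arithmetic, not the underlying per-animal quantification (raw Ct values are
  not public).
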