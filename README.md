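# mitosignal

Peripheral-blood mitochondrial DNA copy number as a biomarker of cerebral
mitochondrial dysfunction after traumatic brain injury — the full analysis
chain as a tested Python package.

After brain injury, damaged cells release mitochondrial damage-associated
molecular patterns; the relative mtDNA copy number measured in whole blood
rises, and the size of that rise tracks how far brain tissue respiration falls
below sham levels. Turning that observation into an assay requires four
computational steps, all implemented here:

1. **NUMT-free primer design** (`mitosignal.primers`) — screen the circular
   mitochondrial genome for regions with no near-identical nuclear copy
   (nuclear mitochondrial segments, NUMTs, confound mtDNA-specific PCR), then
   design 25–30 bp primer pairs with hydrolysis probes inside those regions
   and verify their nuclear specificity exhaustively.
2. **Relative quantification** (`mitosignal.qpcr`) — comparative-Ct analysis
   of triplicate qPCR tables: RQ = 2^−ΔΔCt with ΔCt = Ct_target − Ct_16S
   against a calibrator sample, pooled group statistics (mean ± SEM), and
   per-animal post-minus-pre deltas.
3. **High-resolution respirometry** (`mitosignal.respirometry`) — from a
   closed-chamber oxygraph record of a substrate-uncoupler-inhibitor
   titration (SUIT): O2 calibration, Savitzky–Golay oxygen flux, phase
   segmentation at titration events, most-stable-plateau extraction, and the
   respiratory profile OXPHOS_CI+CII, LEAK_CI+CII, RCR = OXPHOS/LEAK.
4. **Cohort statistics** (`mitosignal.stats`) — exact small-sample Wilcoxon
   signed-rank and Mann–Whitney U tests (full enumeration nulls),
   repeated-measures ANOVA across genes, and the Pearson association between
   each animal's ΔRQ and its sham-referenced respiratory deficit
   (sham mean − post-injury respiration).

A synthetic-data module (`mitosignal.synthetic`) generates truth-known inputs
for every stage — genomes with planted, partially diverged NUMTs, triplicate
Ct tables, SUIT traces with known plateau fluxes, and cohorts with a
prescribed ΔRQ–Δflux correlation — so the whole chain is verifiable against
known ground truth. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/02_design_primers.py
python analysis/03_quantify_mtdna.py
python analysis/04_respirometry.py
python analysis/05_correlate_biomarker.py
```

The drivers write under `results/`. Representative output (seed 0):

```
designed 15 primer pairs across 3 unique regions
top pair (region1): CGGGGATAGCCATAGTGATCCCTTAAG / CAGTTTCTCCTTTGGCCCATTATCCG
  amplicon 111 bp, Tm 58.0/58.0 C, penalty 0.019
  best nuclear identity fwd/rev: 0.667/0.731
```

The screen found three mtDNA regions free of the planted NUMTs and the top
pair's best nuclear match is far below priming range (identity ≤ 0.73).

```
phase fluxes (pmol O2 / s / mg):
  baseline: 14.97, truth 15.0 (0.21% off)
  OXPHOS_CI+CII: 82.56, truth 82.6 (0.05% off)
  LEAK_CI+CII: 13.96, truth 14.0 (0.30% off)
RCR = 5.915 (OXPHOS 82.6 / LEAK 13.96)

RNR-6h: r = 0.966 (p = 0.034, n = 4); generator truth r = 0.8
```

Plateau fluxes are recovered within a fraction of a percent of the planted
truth, and the association step recovers the generator's biomarker–deficit
correlation (at n = 4 the estimate is noisy, as expected).

The same stages are available as a CLI:

```bash
mitosignal simulate --seed 0 --out out/
mitosignal design --mito out/mito.fa --nuclear out/nuclear.fa --out out/design
mitosignal quantify --ct out/ct_table.csv --calibrator CAL --out out/q
mitosignal respire --trace out/trace.tsv --out out/r
mitosignal correlate --cohort out/cohort.csv --out out/c
mitosignal reproduce-paper
```

`mitosignal reproduce-paper` recomputes the pooled relative copy-number
aggregates from the packaged per-gene group means: the pre-injury pool
(nine per-gene means weighted by group sizes, n = 39 values) gives 0.8403,
and the post-injury pools give 2.0667 (diffuse injury, 6 h) and 1.3500
(focal injury, 25 h).

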