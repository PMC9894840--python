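# targetms

Desk-scale real-time targeted proteomics for multiplexed (TMT) samples.

Targeted pathway proteomics asks for the abundances of a specific protein
cohort — a kinase family, a metabolic pathway — across many samples at
once, without synthetic internal standards. `targetms` implements the full
decision stack of a real-time acquisition controller for that problem and
pairs it with a discrete-event virtual LC-MS/MS instrument, so the logic is
executable, testable and reproducible without a mass spectrometer. It is
written for proteomics method developers and computational scientists who
want to study, extend or verify real-time acquisition strategies.

## What it does

* **Libraries** (`targetms.libraries`) — build paired *spectral* and
  *elution* libraries from search-result PSM tables: one best-PSM spectrum
  per unique peptide/charge, and an elution-order bin
  `floor(id_time / bin_width)` per peptide (30-s bins by default).
* **Assays** (`targetms.assay`) — turn a protein list into an executable
  assay: up to 3 peptides per protein, each with its elution bin, precursor
  m/z and top library fragments, plus persistent close-out state.
* **Virtual instrument** (`targetms.sim`) — a ground-truth multiplexed
  sample (Gaussian elution peaks, per-channel abundances, co-isolation
  interference, AGC fill model, Poisson noise) answering MS1 / PRM /
  MS2 / SPS-MS3 scan requests deterministically under a seed.
* **Controller** (`targetms.controller`) — the real-time loop: periodic
  elution calibration from abundant MS1 peaks (monotone running-median
  elution point), ion-trap PRM monitoring of targets within ±3 bins,
  library-cosine identification (cosine > 0.9 and > 60% coverage of
  high-abundance fragments), SPS ion purity selection (≥ 0.75 per ion,
  up to 10), ultra-long (2000 ms) MS3 quantification, and close-out.
  Plus a top-N DDA baseline with dynamic exclusion (120 s, ±7 ppm) and
  250-ms MS3 fills for comparisons.
* **Quantification** (`targetms.quant`) — reporter extraction (±0.003 Da),
  event filters (summed SN > 100 / > 160 for TMT11 / TMTpro16, purity
  > 0.7), top-3 aggregation by matched fragments, column normalization,
  blank-channel interference subtraction, protein rollup, and group
  summaries (ratios, CVs, t-tests).

The scientific background, estimator definitions, instrument-model
constants and known limitations are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example: the 1:2:4 spike-in benchmark

Twelve spike peptides are mixed at ratios 1:2:4 in triplicate across the
middle nine channels of a TMT 11-plex (flanking channels blank), in a 1:1
whole-proteome background; the full targeted run plus quantification
pipeline recovers the design:

```python
from targetms.workflows import spikein_workflow

r = spikein_workflow(seed=1)
print(r["n_spike_quantified"], "spike peptides quantified")
print(r["summary"][["mean_1x", "mean_2x", "mean_4x",
                    "ratio_2x_vs_1x", "ratio_4x_vs_1x"]].round(2).head(4))
print("mean 4x/1x:", round(r["ratio_4_vs_1"], 3),
      " mean 2x/1x:", round(r["ratio_2_vs_1"], 3))
```

prints

```
12 spike peptides quantified
                    mean_1x  mean_2x  mean_4x  ratio_2x_vs_1x  ratio_4x_vs_1x
AISQEEGIEAHDFK/2      34.30    68.60   137.20             2.0             4.0
ESQFYHYNEIEHNYYK/2    26.52    53.05   106.09             2.0             4.0
ETALDFYIQYYDHYR/2     31.25    62.51   125.01             2.0             4.0
FGEWNGTYGWTTR/2       28.72    57.43   114.86             2.0             4.0
mean 4x/1x: 4.0  mean 2x/1x: 2.0
```

Each row is one spike peptide; `mean_1x/2x/4x` are the mean reporter
signal-to-noise values of the three channels in each ratio group after
column normalization (against co-targeted 1:1 loading-control peptides) and
blank-channel subtraction. On this noise-free, fixed-seed run the recovered
group ratios equal the design exactly.

## Command line

```bash
targetms build-library psms.tsv --out library.json --scheme TMTpro16
targetms build-assay targets.csv --library library.json --out assay.json
targetms make-scenario --kind spikein --seed 1 --out scenario.json
targetms run --mode targeted --scenario scenario.json --assay assay.json \
             --library library.json --seed 1 --out run1/
```

`run` writes a scan log (JSONL, ground-truth attribution under a `hidden`
key), a decisions TSV and a quant-events TSV.

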