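# Methods

## The acquisition model

`targetms` implements a real-time targeted proteomics controller for
multiplexed (TMT-labeled) samples, together with a virtual LC-MS/MS
instrument rich enough to exercise every decision the controller makes.
The method rests on two observations about bottom-up proteomics: peptide
*elution order* is far more stable across LC runs than absolute retention
time, and a previously acquired fragment spectrum is a sufficient identity
reference. Both are distilled into a paired library:

* **spectral library** — per unique (sequence, variable mods, charge) key,
  the fragment peak list of the single best-scoring PSM from a prior run
  (ties broken by earlier identification time, then key, so builds are
  deterministic);
* **elution library** — the same keys mapped to an elution-order *bin*,
  `floor(identification time / bin width)`, recorded without retention-time
  alignment between fractions.

An assay selects up to *k* = 3 peptides per target protein from the library
(ranked by best-PSM score, then base-peak intensity, then key) and carries,
per peptide, its elution bin, precursor m/z and up to 20 monitored library
fragments. Peptides with fewer than 6 library fragments cannot support PRM
detection and are skipped with a warning.

During acquisition the controller:

1. **Calibrates** every 15 s: the top 6 MS1 peaks get fast ion-trap MS2
   scans, each searched with the real-time scorer; accepted identifications
   are mapped to their library bins and the elution point `c` (in bins) is
   updated as the *monotone running median*: `c <- max(c, median(bins))`.
   Empty episodes extrapolate `c` at an estimated rate (from the last two
   accepted episodes; default 1 bin per bin-width). The median makes single
   mis-identifications harmless; the monotone floor encodes that elution
   never runs backwards.
2. **Detects** by cycling rapid ion-trap PRM scans over every open target
   whose bin lies within ±3 bins of `round(c)`, independent of MS1
   detectability. A PRM matching ≥ 6 monitored fragments (±0.4 Da) promotes
   the target.
3. **Identifies** with a 900-ms Orbitrap MS2: experimental intensities are
   projected onto the library peak positions (±10 ppm, unmatched → 0) and
   the identity is confirmed only when the cosine against the library
   intensities exceeds 0.9 *and* more than 60% of the library fragments with
   relative abundance above 50% of the base peak are present. Both
   inequalities are strict, as is the purity filter below; the only
   non-strict gate is the ≥ 6 fragment count.
4. **Quantifies** with a synchronous-precursor-selection MS3: matched
   fragments are ranked by experimental intensity and kept while their share
   of the ion current within a ±1.0 Da notch is ≥ 0.75, up to 10 ions. The
   MS3 may accumulate ions for up to 2000 ms, which is what gives the method
   its sensitivity on weak precursors. Reporter intensities are read per
   channel and expressed as signal-to-noise.
5. **Closes out** each peptide once an event passes the quantification
   filters; a protein closes when its quantified-peptide count reaches its
   goal (default: all of its assay peptides; configurable to 1). Close-out
   flags are monotone and persist across injections sharing an assay, so
   consecutive runs spend instrument time only on the remainder.

A conventional **top-N DDA baseline** with real-time-search gating is
provided for comparisons: precursors by MS1 intensity under dynamic
exclusion (120 s, ±7 ppm), 35-ms MS2 fills, the same search acceptance
gates, and a short 250-ms MS3 fill. Run on the identical scenario and seed,
it is the reference against which the targeted mode's sensitivity gain on
low-abundance targets is measured.

### The real-time scorer

The scorer is a normalized matched-fragment count (matched library
fragments within ±0.4 Da divided by the number of scored fragments, capped
at 20) standing in for a cross-correlation search engine. The published
acceptance gates are mapped onto it directly: best match must not be a
reversed-sequence decoy, |precursor error| < 10 ppm, peptide length ≥ 7,
score ≥ 0.5, and margin to the runner-up ≥ 0.10. Decoy candidates are
generated per library entry by reversing the sequence (fixed C-terminal
residue) and computing its theoretical b/y ladder; reversal preserves the
precursor mass, so decoys are discriminated by fragments, not by mass. The
scorer sits behind `SearchIndex` and can be replaced without touching the
controller.

## The virtual instrument

Each analyte is a labeled tryptic peptide with a per-channel abundance
vector, a Gaussian elution peak (apex, sigma) and a flux coefficient; its
instantaneous ion flux is `coeff * total_abundance * exp(-(t-apex)^2 / 2s^2)`
(truncated at 6 sigma). Ion accumulation follows a minimal AGC model,
`fill = min(max injection, AGC target / incoming flux)`, so intensities are
linear in fill time below the AGC cap — the property that makes the
2000-ms vs 250-ms MS3 comparison meaningful. MS2-type scans return the
fragment peaks of *everything* co-isolated in the precursor window; the MS3
reporter region sums, per channel, the flux of every co-isolated analyte's
fragments that fall inside the notches weighted by that analyte's channel
fractions — which is exactly how isobaric interference arises in the real
measurement. Every peak carries a hidden attribution map (analyte →
fraction of ion current, summing to 1) that only tests and oracles read.

Numerical/instrument constants, chosen once for realism and fixed:

| parameter | value | rationale |
| --- | --- | --- |
| ion-trap m/z jitter | 0.1 Da (sd) | makes the 0.4 Da coarse tier meaningful |
| Orbitrap m/z jitter | 3 ppm (sd) | makes the 10 ppm fine tier meaningful |
| reporter m/z jitter | 0.8 mDa (sd) | makes the 3 mDa extraction tolerance meaningful |
| scan overheads | 60 / 30 / 120 / 150 ms (MS1 / IT / OT-MS2 / MS3) | duty-cycle realism |
| AGC targets | 2e5 / 5e4 / 1e5 (MS1 / MS2 / MS3) | typical tribrid operating points |
| MS1 / MS2 detection floors | 50 / 2 counts | a finite detection limit so weak precursors are MS1-invisible but PRM-detectable |
| counting noise | Poisson on expected counts (optional) | shot-noise-limited detection |

Mass jitter is part of the analyzer model and is always drawn from the
seeded generator; identical (scenario, request stream, seed) triples
reproduce bit-identical records. FAIMS is an abstract channel label: a scan
only sees analytes with a matching CV, and the default is a single CV.

## Synthetic samples

`make_adh1_scenario` is the in-silico protein-standard spike-in validation:
12 spike peptides at ratios 1:2:4 in triplicate across the middle nine
channels of an 11-plex, the first and last channels blank, in a background
of peptides mixed 1:1 across all channels (default 150 background peptides,
log-normal abundance with log10 sd 0.5, 1200-s gradient, 8-s peak sigma).
A dilution factor scales the spike abundances down, emulating the serial
dilution. `make_proteome_scenario` draws protein abundances log-normally
with log10 sd 1.2 — the spread of deep-proteome iBAQ distributions, several
orders of magnitude across a few hundred proteins — with per-peptide yield
factors (log10 sd 0.3) and uniform apexes. `warp_gradient` applies the
monotone nonlinearity `t' = L * (t/L)^1.15` to all apexes, the
changed-gradient regime that real-time calibration must absorb; its inverse
defines the true current bin for scoring calibration accuracy.

What the generators deliberately do **not** model: isotope envelopes and
charge-state distributions, chromatographic tailing, TMT isotope-impurity
cross-talk, FAIMS physics, and the sheer analyte density of a real tryptic
digest (hundreds of thousands of species). The last point matters when
reading the DDA comparison: with only ~10^3 virtual analytes the baseline
digs deeper than a real instrument would, so the sensitivity gap between
targeted and DDA modes is directionally correct but numerically compressed
relative to real data. Passing tests demonstrate the decision logic and the
filter arithmetic, not instrument-grade performance prediction.

## Quantification pipeline

Reporter signal is extracted within ±0.003 Da per channel and divided by
the scan noise estimate to give SN. Events require summed SN > 100 (TMT11)
or > 160 (TMTpro16) and SPS isolation purity > 0.7 — the event purity is
the intensity-weighted mean of the selected SPS ions' notch purities,
computed from the controller-visible MS2, never from hidden attribution.
The SN filter is applied *before* top-3 selection (the order is not fixed
by convention; this choice is documented and tested). Per peptide, the top
three events by matched fragment count (ties to higher summed SN, then
earlier scan) are summed channel-wise. Column normalization rescales each
channel so column sums equalize at the mean original sum; when loading
controls are present (1:1 background peptides targeted alongside spikes),
factors are computed from the control rows only and applied to all rows so
deliberate ratio designs are not flattened. Blank-channel subtraction
removes, per row, the mean blank signal from every non-blank channel,
floored at zero. Proteins roll up as channel-wise sums over protein-unique
peptides; shared peptides contribute to no protein and are reported.

## Problem sizes

The bundled end-to-end checks use desk-scale runs chosen to exercise every
code path with comfortable statistics: the spike-in benchmark runs 12 spike
+ 150 background peptides over a 1200-s gradient; the calibration-warp
check runs 250 peptides over 1800 s (~120 episodes); the sensitivity
comparison runs 500 proteins x 2 peptides with a 50-protein assay spanning
the abundance ranking over 1800 s; close-out campaigns run 60 proteins x 2
peptides over 900 s for three injections.

## Known limitations and open choices

* The per-ion SPS purity threshold (0.75) and notch half-width (1.0 Da) are
  package choices; only the existence of "a fixed purity threshold" is
  conventional.
* Close-out supports both peptide-level and protein-level completion; the
  default protein goal is all assay peptides of the protein.
* Elution bins are taken from the best-scoring PSM's identification time;
  when a peptide is identified in several fractions, other conventions
  (earliest, consensus) are defensible but would decouple spectral and
  elution provenance.
* Fragment matching uses singly charged b/y ions only; higher fragment
  charges are computed on request but not monitored by default.
* The calibrated window is parameterized in bins (±3); wall-clock window
  widths follow as `bin width x 7`, so narrow-window (short-bin) and
  wide-window (long-bin) operation differ only in `bin_width_s`.
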