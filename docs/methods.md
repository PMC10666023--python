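# Methods

## The measurement being modeled

Meiotic recombination starts with programmed DNA double-strand breaks
(DSBs) made by SPO11 at narrow hotspots. Each break is resected 5'->3',
leaving 3' single-stranded tails; exonuclease-blunted end sequencing
removes the single-stranded DNA and sequences the blunted duplex ends, so
a top-strand (plus) read marks a *rightward* resection endpoint and a
bottom-strand (minus) read a *leftward* one. Reads very close to the
hotspot center instead derive from recombination intermediates ("central
signal"), and every library carries a DSB-independent uniform background.

`dsbend` implements the end-signal analysis of such data — strand-split
RPM tracks, hotspot-centered co-oriented profiles, resection-length
distributions, peak calling, hotspot-class overlap and PAR signal
summaries — together with a generative simulator so that every stage is
exercised and tested without external sequencing data.

## The generative model

For a genotype with `total_reads` reads:

1. Reads are split multinomially into PRDM9-hotspot, default-hotspot and
   background categories with fractions `(frac_prdm9, frac_default,
   frac_background)` summing to 1.
2. A hotspot-assigned read picks a hotspot of its class with probability
   proportional to heat; hotspots inside the pseudoautosomal region (PAR)
   have their heat multiplied by `par_boost`.
3. The DSB center is the hotspot center plus Gaussian jitter
   (sd `dsb_jitter_sd` = 50 bp by default).
4. With probability `frac_central` the read is a central signal: strand
   by fair coin, position uniform within `center ± central_halfwidth`
   (100 bp). Otherwise it is a resection endpoint: strand by fair coin,
   length `l ~ Gamma(resection_shape, resection_scale)` nt, position
   `center + l` (top) or `center - l` (bottom).
5. Background reads are uniform over the genome, fair-coin strand.
   All positions are rounded to integers and clipped to chromosome
   bounds. One seeded `numpy` generator per call; no global state.

The gamma family is a modeling choice: measured mouse resection-endpoint
distributions are unimodal and right-skewed with means near 1 kb, and a
gamma with mean `shape * scale` reproduces that shape while keeping the
mean a single interpretable product. Defaults are shape 16, scale 50 nt
(mean 800 nt, sd 200 nt).

### Genotype presets

| preset              | frac_prdm9 | frac_default | frac_background | resection mean | par_boost |
|---------------------|-----------:|-------------:|----------------:|---------------:|----------:|
| `wildtype`          | 0.75       | 0.05         | 0.20            | 800 nt (16x50) | 8         |
| `ankrd31_null_like` | 0.45       | 0.35         | 0.20            | 700 nt (14x50) | 0         |
| `ea_like`           | 0.72       | 0.08         | 0.20            | 800 nt         | 5         |
| `spo11_null`        | 0          | 0            | 1               | —              | —         |

All presets use `frac_central = 0.15` except `spo11_null` (no DSBs at
all). The null-like preset encodes the three contrasts of interest: a
100 nt shorter mean resection, elevated default-hotspot usage, and loss
of PAR signal; `ea_like` keeps a wildtype-like landscape with an
intermediate PAR boost.

### Genomes and catalogs

The built-in `example_genome()` is a 35 Mb, four-chromosome stand-in
(three autosomes plus a 5 Mb sex chromosome carrying a 700 kb PAR — the
mouse PAR's true length). Profile- and peak-scale studies use a dense
catalog (2,000 PRDM9 + 1,000 default hotspots, >=10 kb spacing) so that
2,000 anchors are available for averaging. PAR-scale studies use
`example_catalog()` (270 hotspots), which reproduces realistic hotspot
sparsity — roughly one hotspot per 130-190 kb, so a PAR-length window
holds only a handful — and places the PAR's genome-average expectation of
hotspots (5) inside it by construction, because the real PAR is
intrinsically hotspot-carrying; leaving its representation to a random
draw would make the PAR contrast a test of the catalog sampler rather
than of the signal. Hotspot heats are Gamma(2.5, 1), a heavy-tailed
spectrum like observed hotspot heat maps. Placement enforces a minimum
pairwise spacing exactly via the order-statistics spacing transform
(sample sorted uniforms on the shrunken interval, then re-inflate).

## The analysis path

1. **Coverage.** Each end record increments bin `floor(pos/bin)` on its
   strand; total bin mass equals the record count exactly. RPM
   normalization multiplies by `1e6 / n_mapped`; normalizing twice is an
   error, never a silent rescale. Replicates are averaged after RPM
   normalization; raw counts are pooled for peak calling.
2. **Co-orientation.** For each hotspot, top-strand signal is read at
   offsets `d in [-flank, +flank]` (flank 5,000 bp) and bottom-strand
   signal at `-d`; the flipped bottom is added to the top so both
   resection directions superimpose on one positive-distance axis.
   Averaging across hotspots is unweighted — each hotspot contributes
   equally (heat-weighted averaging is available as an option). Hotspot
   windows crossing a chromosome end are skipped and counted in the log,
   not zero-padded, to avoid biasing the average.
3. **Smoothing.** A Hann (raised-cosine) window rescaled to unit sum,
   applied with reflection padding: unit sum preserves the local mean,
   reflection preserves constants. 151 bp for 1-bp profiles; 51 bins for
   10-bp and 40-bp display tracks.
4. **Background subtraction and peak normalization.** The profile value
   at +2,500 bp from the center estimates background and is subtracted
   (a flank-window-average alternative is not the default: the single
   smoothed value is already a ~151-bp local average). For display
   normalization the profile is divided by its maximum on (100, 2500] bp
   and negatives are clamped to zero, so the resection peak is exactly 1
   and the value at 2,500 bp exactly 0.
5. **Resection-length distribution.** After background subtraction,
   offsets <= 100 bp (central signal) and > 2,500 bp are zeroed,
   negatives clamped, and the remaining signal expressed as fractions per
   100-bp bin: (100, 200], ..., (2400, 2500]. The mean resection length
   is the bin-midpoint weighted mean (midpoint of (a, a+100] is a+50) —
   the histogram is the primary object and the mean a convention on it.
   Genotype comparison reports the difference of means; an optional
   bootstrap over hotspots (default 1,000 resamples, percentile 95% CI)
   treats the hotspot as the unit of replication.
6. **Peak calling.** A fixed 1,000-bp window slides at half-window steps
   over combined-strand raw counts; each window count is tested against
   Poisson with the genome-wide mean rate, p-values are
   Benjamini-Hochberg adjusted across all windows, windows with adjusted
   p < 0.01 are merged when within 500 bp, the summit is the
   maximum-signal bin, and fold enrichment is the merged-interval rate
   over the background rate. This is a minimal, fully specified caller —
   sufficient for genotype-contrast accounting, not a reimplementation of
   any published caller; it has no local-background (MACS-style) model.
7. **Overlap accounting.** Hotspot intervals are `center ± 1,000 bp`;
   any bp of intersection counts, and a peak may overlap both catalogs,
   so both overlaps plus their intersection are reported and the identity
   `n_prdm9 + n_default - n_both + n_neither = n_peaks` holds exactly.

## Numerical and degenerate-input choices

- **Degeneracy floor.** With a stochastic background, the
  background-subtracted window signal is never exactly zero, so
  "no resection signal" is declared when the clamped remaining signal is
  below `resection_min_signal_frac` (default 0.1) of the pre-subtraction
  window total. Background-only libraries fall near 0.02 on the smoothed
  path; genuine signal sits far above 0.5. Degenerate distributions are
  all-zero and flagged, not an error; their mean is undefined.
- **Smoothing leak.** The 151-bp Hann window smears central-signal mass
  past the 100-bp core exclusion: at an extreme central fraction of 0.3
  this biases the estimated mean by ~30 nt (vs ~4 nt unsmoothed, which is
  why the unsmoothed extraction path exists). The bias is common-mode
  between genotypes at equal `frac_central`, so difference-of-means
  estimates are unaffected (the recovered shift is 100 ± a few nt).
- **Windows at boundaries.** Resection histogram bins are right-closed;
  the value exactly at 2,500 bp belongs to the last bin and is zero after
  subtraction by construction.
- **Proportions.** Percentages are rounded half away from zero (8/9 ->
  89, 27/59 -> 46); confidence intervals are exact Clopper-Pearson,
  appropriate at the very small n of cytological counts.
- **Determinism.** Every stochastic operation takes an explicit seed and
  uses a single local generator; identical seeds give byte-identical
  outputs, including pipeline manifests. The `--threads` flag is accepted
  for interface compatibility; hotspot aggregation is vectorized, so
  results never depend on it.

## Problem sizes

Simulation studies run at desk scale by design: a 35 Mb genome, 2,000
profile hotspots, and 100k-500k reads per genotype. These sizes put
Monte-Carlo error well inside every tolerance asserted in the tests
(e.g. the mean of a gamma(16, 50) estimated from ~170k endpoint reads has
a standard error below 1 nt) while keeping any single study under a
minute on one CPU.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure the analysis relies
on: heat-weighted hotspot usage, strand-asymmetric endpoint placement,
a central signal, uniform background, PAR boosting, and genotype
contrasts in resection mean and default-hotspot usage. It does not model
sequence-level effects (mappability, PCR duplicates, GC bias),
chromatin-driven hotspot clustering, per-hotspot resection
heterogeneity, or replicate correlation beyond independent seeds.
Passing tests therefore demonstrate that the estimators recover known
generative truths under the stated noise model — not that real libraries
are free of the biases the generator omits.

## Known limitations

- The resection mean is histogram-based and window-limited: true lengths
  beyond 2,500 bp are excluded by construction (negligible for gamma
  means near 800 nt, a real truncation for much longer resection).
- The Poisson-window caller assumes a globally uniform background; it is
  deliberately simple and replaceable behind `call_peaks`.
- Peak normalization divides by a single smoothed maximum; profiles with
  no signal above background error out rather than returning noise.
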