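# dsbend

Strand-specific analysis of meiotic DNA double-strand-break (DSB)
end-mapping data, for researchers studying recombination initiation and
DNA end resection.

Meiotic DSBs are made by SPO11 at hotspots and resected 5'->3'.
Exonuclease-blunted end sequencing maps the resection endpoints: a
plus-strand ("top") read marks a rightward endpoint, a minus-strand
("bottom") read a leftward one, and reads at the hotspot center derive
from recombination intermediates. `dsbend` turns mapped end positions
into the standard readouts of such experiments:

- strand-split, RPM-normalized coverage tracks (bedGraph);
- hotspot-centered **co-oriented** average profiles: bottom-strand signal
  is flipped across the center so both resection directions superimpose
  on one positive-distance axis, then smoothed with a unit-sum 151-bp
  Hann window;
- **resection-length distributions**: after subtracting the background
  estimated 2,500 bp from the center and excluding the <=100 bp hotspot
  core, the remaining signal is expressed as fractions per 100-bp bin
  over (100, 2500] nt, with mean length
  `sum_i fraction_i * midpoint_i`;
- **peak calls** (sliding-window Poisson test, Benjamini-Hochberg
  adjusted) and their overlap with PRDM9-directed versus "default"
  hotspot catalogs;
- pseudoautosomal-region (PAR) interval signal summaries and exact
  binomial proportion summaries.

A first-class synthetic generator (`dsbend.simulate`) produces genomes,
hotspot catalogs and resected-end reads with the statistical structure
the analysis assumes — gamma-distributed resection lengths, central
signal, uniform background, PAR boosting — plus genotype presets
(`wildtype`, `ankrd31_null_like`, `ea_like`, `spo11_null`), so the whole
pipeline runs and is tested without external data.

## Worked example

```python
from dsbend import *
from dsbend.simulate import genotype_preset

genome = example_genome()                      # 35 Mb, 4 chromosomes, 700 kb PAR
prdm9 = simulate_hotspots(genome, 2000, hclass="prdm9", seed=1)
default = simulate_hotspots(genome, 1000, hclass="default", seed=2)
catalog = HotspotSet.concat([prdm9, default])
cfg = AnalysisConfig()                         # 151-bp Hann, 2.5 kb background, ...

for name in ("wildtype", "ankrd31_null_like"):
    params = genotype_preset(name).replace(total_reads=250_000, seed=7)
    ends = simulate_end_reads(genome, catalog, params)
    track = rpm_normalize(bin_coverage(ends, genome, 1))
    profile = smooth_profile(cooriented_average(track, prdm9, cfg), 151)
    dist = resection_length_distribution(profile, cfg)
    print(f"{name}: mean resection = {mean_resection_length(dist):.0f} nt "
          f"(over {profile.n_hotspots} hotspots)")
```

prints

```
wildtype: mean resection = 787 nt (over 1998 hotspots)
ankrd31_null_like: mean resection = 693 nt (over 1998 hotspots)
```

The wildtype preset generates resection lengths with mean 800 nt and the
interaction-null-like preset 700 nt; the estimator recovers both to
within ~15 nt (the small downward bias is central-signal leakage through
the smoothing window, common to both genotypes), so the genotype
difference — the quantity of interest — comes out at ~100 nt.
Proportion summaries print exact small-n percentages:

```python
>>> s = proportion_from_counts(8, 9)
>>> print(f"{s.percent}% ({s.k} out of {s.n}), 95% CI [{s.ci[0]:.2f}, {s.ci[1]:.2f}]")
89% (8 out of 9), 95% CI [0.52, 1.00]
```

The same stages are available as a CLI (`dsbend simulate / coverage /
profile / resection / resection-compare / peaks / overlap / proportions /
run`); `dsbend run --config run.yaml` executes the whole pipeline per
genotype and writes a deterministic `manifest.json`.

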