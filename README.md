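# magne

Simulation study of how metagenome-assembled-genome (MAG) artifacts bias
estimates of prokaryotic effective population size (Ne).

Population-genetic theory gives `Ne = pi_s / (2 * mu)`: synonymous nucleotide
diversity measured at fourfold-degenerate codon sites, divided by twice the
per-site mutation rate. Isolate genomes sample strain variation faithfully,
but MAGs are consensus assemblies — assemblers collapse polymorphic columns
and drop the most variable gene families entirely. Both artifacts remove
segregating sites, so Ne estimated from MAGs is biased downward. This package
simulates panmictic populations with known diversity, degrades copies of them
the way metagenome assembly does, runs both through an identical
family -> alignment -> pi_s -> Ne pipeline, and quantifies the bias.

## Layout

- `analysis/` — the numbered study scripts (the main entry point):
  1. `01_simulate_population.py` — simulate a population and its MAG twin
  2. `02_estimate_ne.py` — diversity and Ne for both classes
  3. `03_population_delineation.py` — ANI clustering + clonal-complex dereplication
  4. `04_bias_experiment.py` — the replicated isolate-vs-MAG comparison
- `src/magne/` — the library the scripts drive (also a CLI, `magne --help`)
- `scripts/acceptance.py` — one-shot recomputation of the headline numbers
- `docs/methods.md` — model, parameter choices, and limitations
- `tests/` — unit tests plus `test_acceptance.py` (end-to-end checks)

## Worked example

```
$ python analysis/01_simulate_population.py --seed 1
wrote 10 isolates and 10 MAGs under results/01_populations

$ python analysis/02_estimate_ne.py
isolates: median pi_s=0.0198804  Ne=1.389e+06
mags: median pi_s=0.00886922  Ne=6.196e+05
```

The population was simulated with target diversity theta4 = 0.02, i.e. a true
Ne of `0.02 / (2 * 71.57e-10) = 1.40e6`. The isolate class recovers it
(1.39e6); the degraded MAG class — consensus collapse of half the segregating
columns plus probabilistic loss of the most diverse fifth of the families —
comes out 2.2x too low (6.2e5), from the very same underlying population.

The replicated experiment (20 studies, 10 populations per class,
`python analysis/04_bias_experiment.py --seed 1`) makes that systematic:

```
degraded:  mean_bias_isolate = 0.970   mean_bias_mag = 0.414
           frac_replicates_mag_bias_lt_1 = 1.0
           detection_rate_isolate_gt_mag = 1.0   (median Mann-Whitney p = 1.8e-4)
null:      mean_bias_isolate = 0.978   mean_bias_mag = 0.970
           frac_replicates_p_lt_0.05 = 0.10      (20 studies; nominal ~0.04)
regression: isolate slope = 2.30e+06 per divergence %, R2 = 0.993, p = 4.4e-12
```

With no degradation the two classes are statistically indistinguishable; with
realistic degradation the MAG class underestimates Ne by ~2.4x and the rank
test detects it in every study. Across populations spanning
theta4 in {0.005, 0.01, 0.02, 0.04}, isolate-class Ne rises linearly with
whole-genome divergence (100 − ANI%), as expected when both are driven by the
same underlying diversity.

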