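# Methods

This package studies how metagenome-assembled-genome (MAG) artifacts bias
estimates of the effective population size (Ne) of prokaryotic populations,
using fully simulated data. Everything below is the package's own modeling
choice; parameter defaults are stated with their rationale.

## Model

For a neutrally evolving population at mutation-drift equilibrium, the
expected pairwise nucleotide diversity at synonymous sites is

    pi_s = 2 * Ne * mu

so `Ne = pi_s / (2 * mu)`, with `mu` the per-site, per-generation mutation
rate. The default rate is `mu = 71.57e-10` (7.157e-9), a measured prokaryotic
per-site rate; it can be overridden everywhere (`--mu`).

`pi_s` is measured only at **fourfold-degenerate sites**: third codon
positions whose codon belongs to one of the eight fourfold codon families
(GCN, CGN, GGN, CTN, CCN, TCN, ACN, GTN). A column of a codon alignment
enters the mask only if, in every row, the codon is gap-free and unambiguous,
the codon is fourfold-degenerate, and the first two codon positions are
identical across all rows (complete deletion). This guarantees every counted
difference is synonymous regardless of which row is read.

Per family, `pi_s` is the mean pairwise difference proportion over masked
columns (no distance correction by default; a Jukes-Cantor 1969 correction is
available behind `jc69=True`/`--jc69` for users who want divergence-corrected
values). Per population, family values are aggregated by **median** (primary,
robust to a few high-diversity families) and mean (reported alongside). A
population whose median family diversity is zero is reported as Ne = 0.

## Ortholog families and alignment

Genomes carry coding sequences tagged with a family identifier in the FASTA
header (`>genome|family`). A family is **single copy** when it appears exactly
once in every genome; only single-copy families enter the estimate. Members
that fail translation (length not a multiple of 3, internal stop) are
excluded; families with fewer than two valid members are dropped.

Codon-aware alignment translates each CDS, aligns the proteins, and
back-threads the nucleotide sequence through the protein alignment (each
amino-acid gap becomes `---`). The protein aligner is a progressive
profile-profile Needleman-Wunsch with Gotoh affine gaps (BLOSUM62, gap open
10, extend 0.5), with merge order from UPGMA on pairwise p-distances.
Simulated orthologs are indel-free, so equal-length members take a gapless
fast path that is verified against the full aligner in tests.

## Population delineation (ANI-lite)

Average nucleotide identity is computed over the codon alignments of families
shared by each genome pair, weighting by aligned length and skipping gap/N
columns ("ANI-lite": alignment-based, no fragmentation step). Populations are
delineated as single-linkage connected components at **ANI >= 90%**. Within a
component, genomes whose pairwise divergence is below **0.0355%**
(ANI > 99.9645%) form clonal complexes; each complex is collapsed to one
representative (highest completeness, ties broken lexicographically). A
population is retained for Ne estimation only when it has **>= 2
non-redundant members**. Dereplication is idempotent: adding an exact
duplicate genome changes neither the representative set nor the downstream
estimate.

Estimated genome size for real-world quality metadata is
`assembly_size / ((completeness% + contamination%) / 100)`.

## Synthetic populations

`simulate_population` draws a random stop-free ancestor and evolves
`n_genomes` tips. Neutral mutations occur only at third positions of
fourfold-degenerate codons; constrained positions mutate at rate
`theta4 * constrained_rate_ratio` (default 0.1), restricted to substitutions
that keep the codon stop-free.

* **star** genealogy (default): mutations placed independently on each tip
  branch. The per-branch substitution probability is the exact inversion of
  the expected pairwise difference, `b = 0.75 * (1 - sqrt(1 - 4*theta4/3))`,
  so the expected pairwise difference per eligible site equals `theta4`
  exactly, including the chance of two branches hitting the same site.
* **coalescent**: a Kingman tree whose realized branch lengths are rescaled so
  the mean pairwise coalescence time is 1, then the same per-branch mutation
  model is applied along the tree.

`theta4 >= 0.5` is rejected (saturation); fewer than 10 codons per family
triggers a warning (few fourfold sites). Same seed, same bytes.

## MAG degradation

`degrade_to_mag` applies three operators per genome, each with its own
deterministic child stream:

1. **Consensus collapse** (`f`, default 0.5): a fraction `f` of the genome's
   segregating columns (across all families) is overwritten with the
   population majority base (ties to the alphabetically smallest). This
   mimics assemblers collapsing strain variation into a consensus.
2. **Variable-family loss** (`q = 0.2`, `p = 0.5`): the top `q` quantile of
   families by true diversity is deleted with probability `p` per genome,
   mimicking the assembly failure of highly polymorphic regions.
3. **Completeness loss** (`c`, default 1.0 = off): random families are
   deleted until `floor(c * n)` remain.

Both diversity-targeting operators remove segregating sites, so they can only
depress `pi_s` — the mechanism behind the downward Ne bias in MAGs.

## The bias experiment

Each replicate study simulates `n_populations_per_class` populations per
class (default 10), leaves one class as isolates, degrades the other, runs
both through the identical estimation pipeline, and compares:

* **Mann-Whitney U** on Ne (median aggregation primary). The p-value is exact
  (full enumeration via the counting recurrence) when there are no ties and
  `n_x + n_y <= 16`, otherwise the tie-corrected normal approximation with
  continuity correction. Simulated populations are exchangeable by
  construction, so no phylogenetic correction is needed; tree-based
  comparative statistics are deliberately out of scope.
* **OLS regression** of Ne on whole-genome divergence `100 - ANI%` per class
  (p from the slope t-statistic, n-2 df).
* **Bias** per population: `ne_median / ne_true` with
  `ne_true = theta4 / (2 * mu)` using the same `mu` as the estimator, so bias
  isolates pipeline effects from mutation-rate misspecification.

By default all populations in a study share one `theta4` (0.02) so the pooled
rank test compares exchangeable samples; with 10 populations per class its
attained size at alpha = 0.05 is 0.043. Spreading populations across a
`theta4` grid (repeatable `--theta4`, used for the divergence regression)
makes the pooled comparison a slot-matched mixture: still valid for effect
direction, but conservative — interpret its p-values accordingly.

Default study sizes (6 genomes, 50 families x 150 codons) are chosen so the
smallest grid diversity still yields measurably nonzero per-family `pi_s`
while a 200-study null experiment runs in minutes.

## Reproducibility

All randomness flows from one integer seed through labeled SHA-256-derived
child streams (`magne._rng`), so every artifact is byte-reproducible and
sub-operations are independent of each other's draw counts. All derived seeds
are below 2^31.

## Limitations

* The generator is deliberately stylized: no recombination, no indels, no
  gene gain/loss besides the degradation operators, independent families, and
  mutation placed directly from `theta4` rather than from an explicit
  generation-by-generation Wright-Fisher process.
* ANI-lite operates on shared ortholog alignments, not whole-genome
  fragmentation, so absolute values are comparable only within this pipeline.
* The default `mu` is a single point estimate; Ne is only as good as `mu`,
  which is why bias is always reported relative to a truth computed with the
  same `mu`.
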