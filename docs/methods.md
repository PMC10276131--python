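# Methods

## Competition model

A pool of `B` barcoded lineages is propagated through serial transfers.
Lineage `i` carries a baseline fitness `s_i` — the log-linear change of its
frequency per transfer interval — and an environmental sensitivity `g_i`.
Experiments are grouped into batches (replicates performed together); batch
`b` draws a shared deviate `δ_b ~ N(0, σ_batch)` and replicate `r` within it
adds `ε_r ~ N(0, σ_rep)`, giving

```
s_eff(i, b, r) = s_i + g_i · (δ_b + ε_r)
```

Per transfer interval the frequencies update deterministically,
`f_i ← f_i · exp(s_eff_i) / Σ_j f_j · exp(s_eff_j)`, followed by a
multinomial bottleneck of `bottleneck_size` cells. `bottleneck_size = 0` is
a sentinel selecting the exact (infinite-population) recursion, under which
the log-frequency-ratio slope equals `s_eff` by construction — this closed
form is the oracle for the simulator tests. Fractional gaps between
recorded timepoints grow deterministically without a bottleneck; one
bottleneck is applied per completed transfer.

Reference lineages are pinned at `s = 0`, `g = 0`. Because every mutant
shares the deviate `δ_b + ε_r` (scaled by its own `g_i`), mutant classes
move up and down together across replicates — the covariance signature of a
batch effect — while differences between mutant classes with equal
sensitivity cancel it.

Time is measured in transfer intervals; `generations_per_interval`
(default 1) rescales fitness units if the user prefers per-generation
values. No conversion to multiplicative (percent-of-reference) fitness is
applied anywhere; all outputs are log-slopes.

## Default pool

`make_pool` builds the default study pool of 500 lineages:

| group       | n   | s (per interval)      | g | note                                  |
|-------------|-----|-----------------------|---|---------------------------------------|
| reference   | 40  | 0                     | 0 | spiked in at 10% combined frequency   |
| IRA1-like   | 21  | N(0.69, 0.01)         | 1 | strongly adaptive (~2× per interval)  |
| GPB2-like   | 13  | N(0.35, 0.01)         | 1 | intermediate                          |
| IRA1non*    | 6   | one shared draw       | 1 | engineered identical mutation         |
| IRA1mis*    | 8   | one shared draw       | 1 | engineered identical mutation         |
| other       | rest| N(0, 0.05)            | 1 | weakly selected background            |

Lineages of an engineered set carry the same mutation, hence exactly one
true fitness value per set: the spread of their estimates within one
experiment is pure measurement noise, which is what makes the
within-experiment SD category interpretable. The IRA1/GPB2 classes carry
different mutations of similar effect (within-gene SD 0.01). The reference
block is spiked in at a combined 10% so the benchmark stays well covered
even as adaptive lineages expand; all other lineages start at equal
frequency. These choices emulate a pooled yeast competition with a few
hundred lineages, strongly adaptive classes around twice the reference
fitness, and high per-barcode coverage.

Default batch-effect scales in the multi-batch preset are
`σ_batch = 0.10`, `σ_rep = 0.03` — environmental variation visibly larger
between batches than between replicates, and both resolvable above the
sampling noise at the default depth.

## Sequencing and index misassignment

Sequencing is a two-stage sampling process per sample: `M` template
molecules are drawn multinomially from the barcode frequencies
(`M = reads/duplication_rate` unless set explicitly) and tagged with
uniform random UMIs (default 8 nt; collisions are allowed — deduplication
is exact string matching, no error model); then `reads_per_sample` reads
are drawn multinomially over molecules, so PCR duplicates share a UMI.

The amplicon is modeled as `[N][F][ left 40 bp | middle 167 bp | right 40 bp ][R][S]`
where F/R are inline indices, N/S Illumina adapter indices, and the barcode
(26 nt) sits centered in the homologous middle region. Each read
independently undergoes at most one event:

- **template switching** (prob. `p_template_switch`): a partner read is
  drawn uniformly from the whole pooled lane (hence frequency-weighted);
  the breakpoint is uniform over the 247-bp amplicon. A middle breakpoint
  exchanges the entire `(R, S)` half (and the barcode, if it lies on the
  partner's side of the breakpoint); a flank breakpoint exchanges only the
  outer Illumina index on that side, which is why 80/247 ≈ 32.4% of
  switches present exactly like index hopping. The expected ratio of
  single-swap-presenting to cross-end-presenting switches is
  80/167 ≈ 47.9%.
- **index hopping** (prob. `p_hop`): one of N/S (equal odds) is replaced
  by a uniform draw from the scheme's pool (possibly the same value).

An event is *hidden* when the resulting tuple still equals the origin
sample's own tuple (same-sample partner or same-index redraw); hidden
events are undetectable by any index check but still scramble within-read
associations. Truth labels (origin, event, partner, breakpoint region,
hidden) live in a sidecar and never reach analysis-facing outputs.

Because each read suffers at most one event, the double-swap category can
only be produced by exotic inputs, not by the generator — consistent with
treating observed double swaps as multiple independent events or
contamination, which this model does not attempt to reproduce.

## Index schemes and swap classification

Three schemes are supported; samples are identified by
`(F, N, R, S)` tuples of opaque identifiers. Primer accounting counts one
oligo per distinct identifier per side: standard unique dual indexing needs
`2 × n_samples` primers (192 for 96 samples); the nested scheme — each F
exclusively paired with one N, each R with one S, pairs combined
combinatorially — needs only the sum of the pool sizes (12+8+12+8 = 40 for
the same 96 samples).

Classification follows a strict precedence: unmatched (foreign index) →
correct → template switch (valid `(F,N)` half + valid `(R,S)` half, but no
such sample) → single Illumina / single inline swap (exactly one position
differs from some sample) → double swap (two positions) → unmatched. Ties
among candidate samples cannot change the class (it depends only on the
mismatch pattern); when both an Illumina-position and an inline-position
single-mismatch explanation exist, the Illumina explanation wins (the far
more common mechanism). Three or more mismatches are unmatched. The
classifier is verified against an exhaustive minimal-explanation search on
all schemes with ≤ 12 samples.

Two emergent properties worth knowing:

- On a *saturated* nested grid (all row×column combinations used as
  samples), a middle-breakpoint chimera lands exactly on a third sample's
  tuple and is silently accepted; nested UDI's detection advantage over
  plain combinatorial indexing then comes from the flank/hop single swaps,
  which break the inline/Illumina pairing. Detection power equals standard
  UDI only when the used combinations are sparse in the grid (e.g. every
  index used once).
- At equal true rates, a lane with fewer samples *detects* a smaller
  misassigned fraction: more template-switch partners are same-sample and
  more hop redraws hit the same value, so more events are hidden. A
  small-sample lane measures the mechanism mix well but underestimates the
  rate.

`collapse_to_combinatorial` reassigns reads by `(N, S)` alone, emulating
an analysis that ignores inline indices: every UDI-detectable swap is
re-admitted and credited to the sample owning that Illumina pair. On a
multiplexed trajectory lane this relocates reads between timepoints,
flattens frequency trajectories, and systematically shrinks the inferred
fitness magnitude of the top lineages — quantified in the test suite by
running nested and collapsed demultiplexing on identical reads.

## Fitness inference

Frequencies use a pseudocount: `f_i = (c_i + a)/(C + a·B)` with `a = 0.5`
by default, so zero-count timepoints are retained (and flagged) rather than
dropped. Estimates on lineages with all counts ≥ 50 move by < 10⁻³ as `a`
varies over [0.1, 1].

**Reference mode.** The references are pooled by summing counts — the
benchmark otherwise loses coverage exactly when the adaptive lineages take
over — and `s_i` is the OLS slope of `ln f_i(t) − ln f_ref(t)`. A reference
aggregate with a zero raw count at any timepoint is an error that points
the user to mean-fitness mode.

**Mean-fitness mode.** Fixed-point iteration: initialise `s` from raw
log-frequency slopes; repeat x̄(t) = Σ fᵢ(t)sᵢ, X(t) = ∫₀ᵗ x̄ (trapezoid),
re-fit `s_i` as the slope of `ln f_i(t) + X(t)`, until max|Δs| < 10⁻⁶
(≤ 100 iterations). The model is identified only up to an additive
constant — shifting all `s_i` and x̄ together changes nothing observable —
so the scale is anchored by pinning x̄(t₀) = 0 each iteration; without the
anchor the iteration drifts along the unidentified direction indefinitely.
Reported fitnesses are therefore relative to the initial population mean;
differences between lineages, and the constant offset to reference-mode
estimates, are anchor-independent. At the fixed point
Σ fᵢ(t)sᵢ = x̄(t) holds.

**Fold change.** `s_fc = Δ ln(f_i/f_ref) / Δt` between two chosen
timepoints — cheaper but noisier than the multi-timepoint slope (verified
by Monte Carlo in the tests).

**Standard errors.** `std_error` is the larger of the residual-based OLS
standard error and a delta-method propagation of per-timepoint counting
variances (`var[ln f] ≈ 1/c_i + 1/c_ref`). With 5 timepoints the residual
variance has only 3 degrees of freedom and its ±2·SE intervals would cover
well below nominal; the counting term restores calibration (empirically
≈ 94% of well-covered lineages fall within 2·SE of truth) while the
residual term still captures super-multinomial trajectory noise such as
bottleneck drift. OLS is unweighted by default; lineages with mean
coverage below 10 reads/timepoint are estimated but flagged
`low_coverage`.

## Noise decomposition

All standard deviations are sample SDs (n−1) over groups with ≥ 2 members;
smaller groups are skipped and logged.

- **within experiment**: SD of `s_hat` across lineages of one genotype
  group within one replicate experiment — with identical genotypes this is
  sampling noise only.
- **across replicates**: SD of one barcode's `s_hat` across the replicates
  of one batch — adds replicate-level environmental noise.
- **across batches**: SD of one barcode's `s_hat` across all replicate
  experiments — adds batch-level environmental noise.

The `nine-batches` preset mirrors a 28-experiment, 9-batch design in which
the within-experiment category is evaluated for the GPB2 group (28
experiments) and the two engineered sets (4 experiments each), and the
across categories for the 21 + 13 IRA1/GPB2 barcodes: exactly 36, 306, and
34 observations.

`replicate_r2` computes the squared Pearson correlation of log10
pseudo-frequencies between technical replicates (raw-frequency transform
available); barcodes absent from one member are retained through the
pseudocount, since dropping them biases R² upward. `genotype_contrast`
reports per-replicate mean differences between two genotype groups and
their SD — shared environmental deviates cancel in the difference.
`estimate_condition_effect` returns the difference of condition means with
its naive SE (σ/√n per condition) and flags designs where no batch
contains both conditions; in such confounded designs the condition effect
and the batch effect are inseparable and the naive SE badly overstates
precision. Boxplot summaries use type-7 (linear interpolation) quartile
hinges, whiskers at the most extreme values within 1.5×IQR of the hinges,
and notch half-width 1.58·IQR/√n.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → demux → fit → decompose, writing every
stage's tables (TSV/CSV/JSON) stamped with the configuration hash and
seed; identical configurations reproduce byte-identical tables. All
randomness flows from numpy `default_rng` seeded from the single run seed.
The multi-batch presets sample counts directly from the true frequencies
(multinomial per sample); the read-level path (UMI-tagged reads, index
misassignment, full demultiplexing) is enabled by `read_level: true` and
used by the misassignment-demo preset (8-sample all-unique lane, 5,000
reads/sample), matching how mechanism studies are actually run at small
sample counts.

Default problem sizes — 500 lineages, 5 timepoints, 10⁵ reads/sample, 28
replicate experiments; ≥ 10⁵ reads for breakpoint simulations — keep every
analysis well resolved while the full test suite and the acceptance script
run in well under a minute each.

## What the generator does and does not emulate

The simulator reproduces the *statistical structure* of bar-seq noise:
multinomial sampling cascades, UMI duplication, batch/replicate covariance
of fitness, uniform-breakpoint template switching, and index hopping. It
does not model base-call errors or quality scores, barcode sequence errors
or chimeric barcodes (the barcode is taken whole from one parent), UMI
errors, PCR amplification bias or cycle-number effects, cluster chemistry,
or rate differences between flow-cell technologies beyond the configurable
`p_template_switch`/`p_hop`. Passing tests therefore demonstrate that the
*analysis* is correct under the stated noise model, not that real lanes
have any particular misassignment rate; on real data, rates must be
measured, not assumed, and sequence-level error correction is a separate
upstream concern.

## Known limitations

- Fitness inference assumes log-linear trajectories; frequency-dependent
  selection or strong clonal interference over the sampled window violate
  the model (the mean-fitness mode tracks the population but `s_i` is
  still a single number per lineage).
- The variance decomposition is descriptive (no REML/mixed-model variance
  components, no multiple-testing machinery).
- Index identifiers are compared as exact strings; sequence-level index
  mismatch tolerance is out of scope, as is demultiplexing by alignment.
- At most one misassignment event per read; multi-event reads (a real but
  rare source of double swaps) are not generated.
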