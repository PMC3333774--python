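# Methods

## Problem setting

A pooled shRNA barcode screen infects a cell population with a lentiviral
library of hairpin constructs, lets selection act, and reads out each
construct's fitness effect by sequencing the 19-nt sense sequences PCR'd
out of genomic DNA. Deconvolution is a counting problem: assign each short
read to the hairpin that produced it, compare counts between a reference
and a test arm, and decide which hairpins are genuinely depleted or
enriched. `shscreen` implements that chain — alignment, normalization,
hit calling — plus a generative simulator used to measure the chain's
detection performance on screens with known, engineered depletion.

## Read alignment

Reads are 26 bases with the sense sequence at positions 3–21 (1-based,
inclusive; configurable). Qualities are ignored throughout: identical
trimmed reads are binned and each distinct 19-mer aligned once, which is
exactly equivalent to per-read alignment. A read with more than `max_n`
(default 2) uncalled bases in the 19-base window is filtered. The aligner
computes hamming distance to every library sequence with a cap
(`max_mismatch`, default 2) and uses best-stratum semantics: the read is
assigned only if a single library sequence attains the minimal distance;
ties at the minimum are ambiguous even if separable at larger distances.
An uncalled base mismatches everything, including another N — an uncalled
position carries no identity evidence, and this composes conservatively
with the cap (a read with 2 Ns can carry no further substitutions and
still be assigned). Every read lands in exactly one of
{filtered, unique, ambiguous, unmapped}; the four counts sum to the total
read count exactly, and this conservation is asserted at run time.

Two accelerations, both semantically transparent and tested against a
brute-force all-pairs oracle: a hash index short-circuits distance-0
assignment (duplicate library sequences make an exact match ambiguous at
distance 0), and the remaining bins are scored against the whole library
in vectorized batches. Reads are aligned as sequenced; no reverse
complement is searched, because the sequencing primer fixes orientation.

The trim window coordinates, the mismatch cap of 2, and the two-N
allowance are appropriate for a library whose sense sequences are almost
all separated by pairwise distance > 2; `edit_distance_profile` is the QC
tool for verifying that property on a new library before trusting the cap.

## Normalization and scoring

Pipeline order is fixed: abundance filter → log2(count + pseudocount) →
per-replicate log ratio M = log2(test) − log2(reference) and mean
abundance A = (log2(test) + log2(reference))/2 → loess detrend of M on A
per pool → MAD rescale per pool → optional quantile normalization across
replicates → summarization (median, or a SAM-style regularized t).

Parameters that matter:

* **pseudocount** (default 0.5): keeps zero counts finite on the log
  scale; any positive value works, 0.5 adds the least distortion to the
  counts the screen actually uses.
* **min_ref_count** (default 100 reads): hairpins whose mean reference
  count is below this are flagged out of loess, MAD estimation, and hit
  calling (but kept in the output, flagged). The log ratio of a
  ~100-count hairpin has ~0.2 log2 units of pure sampling noise; below
  that the score is mostly noise.
* **loess span** (default 0.5) and **robustness iterations** (default 3):
  the abundance-dependent bias seen in MA plots of real screen arms is
  smooth and large-scale, so a wide span suffices. The bisquare
  robustness iterations are not cosmetic: genuinely depleted hairpins are
  outliers with respect to the local null trend and concentrate at low A
  (depletion moves A left by |log2 d|/2 per arm). A non-robust fit
  follows them and subtracts away part of the very signal being measured
  — in simulated engineered-depletion screens the zero-false-positive
  FNR of the 75%-depleted group degrades by an order of magnitude when
  iterations are set to 0. Three iterations is the classic lowess
  setting. The fit is returned alongside the residuals so before/after
  MA diagnostics can be plotted.
* **MAD rescale**: z = (score − pool median) / (1.4826 · MAD). The
  normal-consistency constant makes the scale interpretable as a robust
  standard deviation, so scores are robust z-scores and pools are
  directly comparable. Degenerate pools (MAD 0) are an error, not a NaN.
* **quantile normalization** (optional, off by default): classic
  order-statistic averaging; ties within a column receive the mean of the
  reference values their ranks span, so sorted columns are identical
  afterwards, exactly. A plain rank replacement is available as
  `method="rank"` for users who want monotone harmonization without
  imposing a common distribution.
* **regularized t** (`summarize_replicates(..., "regularized_t")`):
  d = mean / (s0 + s/√n) with s0 the 90th percentile of per-hairpin
  standard deviations — additive shrinkage that keeps low-variance
  hairpins finite. The median is the default summary; with one replicate
  it degenerates gracefully to that replicate.

Scores are oriented test − reference: depletion is negative.

## Hit calling

Hairpin hits come from a quantile–quantile departure rule. The reference
line is the robust fit (median, 1.4826·MAD); observed order statistics
are compared with expected normal quantiles at Blom plotting positions.
Walking from each tail inward, the i-th point is compared with the
expected extreme of the sample remaining after the i points already
walked past are trimmed. Trimming is what makes the rule usable: true
hits occupy the outermost ranks, and without trimming they displace the
plotting positions of genuine null extremes, making the null's own tail
look deviant and producing false calls adjacent to any real hit cluster.
The outermost run of points deviating by more than `deviation_k` (default
0.5 score units) is called; runs shorter than `min_run` (default 3) are
treated as extreme-value fluctuation of a sample minimum/maximum, not a
distributional departure, so an isolated wobbly extreme never becomes a
hit. Any QQ-based rule is an interpretation of a visual method; this one
is deterministic, has two interpretable knobs, and a fixed robust-z
cutoff (`fixed_z_threshold`, default |z| > 3) is provided as the blunt
alternative.

Gene scores use a weighted average of the two most extreme hairpin scores
per gene in the tested direction (weights 0.75/0.25 by default; alpha = 1
reduces to the single most extreme hairpin). Significance comes from
size-matched permutations over the pool's hairpin scores,
p = (1 + #{permuted ≤ observed}) / (1 + N), with Benjamini–Hochberg
q-values across genes. Single-hairpin genes are scored but flagged; their
score is not shrunk.

## Simulator

The generative model, per screen:

* starting abundance p_h ∝ exp(Normal(0, σ_a)), σ_a = 0.5 natural-log
  units by default — roughly a 30-fold spread across a 10k pool;
* a depletion design maps chosen hairpins to retention d_h ∈ (0, 1]
  (`make_depletion_design` draws disjoint random groups, e.g. ~1,000
  hairpins each at 75%, 50%, 25% retention in a 10,000-hairpin pool);
* per sample, expected fractions q_h ∝ p_h·d_h (test arm) renormalized,
  and counts ~ Poisson(R · q_h · 2^Normal(0, σ_n)). R defaults to 10⁷
  reads. σ_n (default 0.08 log2 units) is a calibration, not a measured
  value: it subsumes PCR amplification noise, infection stochasticity,
  and culture drift in one multiplicative extra-Poisson term, at a level
  that reproduces observed null log-ratio spread (zero-FPR detection of
  50% depletion with a few-percent FNR while 25% depletion is only
  partially detectable). Poisson rather than multinomial sampling keeps
  cells independent; at these depths the difference is negligible.
* FASTQ emission builds 26-mers (2-base flank + sense + 5-base flank;
  the flanks are arbitrary stand-ins for the vector's constant regions),
  with per-base substitution errors uniform over the three alternative
  bases (default 0.5%) and uncalled bases (default 0.1%); qualities are
  a constant placeholder because the aligner ignores them.

Randomness uses one master seed with deterministic per-(purpose, arm,
replicate) child streams, so adding replicates never changes earlier
samples. `subsample_counts` models reduced sequencing depth as binomial
thinning, which maps Poisson(λ) to Poisson(fλ) exactly and composes.

What the simulator does **not** model: multiple viral integrations per
cell, cell-growth dynamics over passages, GFP/puromycin selection, and
sequence-composition-dependent PCR or sequencing bias. The last point
matters for interpretation: simulated screens have no systematic M-vs-A
trend, so passing the loess tests here shows the fit does no harm and
removes injected bias, not that real instrument bias looks like the
injected one. Detection numbers from the simulator characterize the
scoring chain under the stated noise model, not any particular
instrument or library prep.

## Detection evaluation

`evaluate_detection` sweeps score thresholds (depletion direction: call =
score < t) against the simulation truth. Per retention group it reports
the FNR at the most permissive threshold admitting zero false positives
(t = the minimum non-manipulated score, strict inequality), the FPR at
the threshold where the group's FNR first reaches ≤ 5%, and the group
mean of raw test/reference count ratios (zero-reference hairpins are
excluded and counted). Note the raw ratios include the compositional
renormalization — depleting 10% of a pool to 25% retention makes every
other hairpin relatively more abundant, so the measured group ratio sits
above the nominal d — which is also true of the real experiment.
Replicate reproducibility is the squared Pearson correlation of
loess-normalized log ratios between two replicates. The pooled ROC is
monotone by construction and checked as such.

## Problem sizes and numerical choices

The bundled performance tests and the acceptance script use the default
calibration at full design size (10,000 hairpins, 10⁷ reads per sample,
10 seeds for stochastic quantities) — count-level simulation makes each
seed a sub-second computation — and 10⁶ reads for the FASTQ-level
alignment benchmark. Loess uses the standard linear-interpolation
speedup (`delta` = 1% of the A range) above 5,000 points; the numerical
effect is far below every tolerance used. Thresholds on sorted score
arrays use strict/non-strict inequalities exactly as documented above;
ties at a threshold are never called.

## Known limitations

* With very large depleted fractions (a third of the pool), no
  truth-blind baseline is unbiased for the shallowest group: robust
  loess still absorbs ~0.1 log2 units of a 25%-depletion signal. The
  parameter-recovery guarantee is therefore stated for sparse depletion
  (~1% of the pool per group), the regime screen normalization assumes.
* Under the default calibration the replicate r² of the full three-level
  engineered-depletion design plateaus near 0.89 (the Poisson-only
  ceiling is ~0.97); higher observed reproducibility implies a smaller
  extra-Poisson noise term than the default σ_n.
* The QQ rule calls nothing when fewer than `min_run` points depart —
  a screen with one or two true hits needs the fixed-z fallback or gene
  level evidence.
* `loess_normalize` is local-linear only; `degree` other than 1 is
  rejected rather than silently approximated.
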