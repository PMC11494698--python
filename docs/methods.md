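# Methods

## The assay and its quantification

The quantified experiment is a Gal4/UAS transient repression assay: a
candidate peptide motif fused C-terminally to the Gal4 DNA-binding domain
competes a GFP reporter down from its Gal4-only baseline. Each construct is
measured in 3 plants (biological replicates) with 8 leaf disks per plant
(technical replicates). Technical replicates are averaged first so that each
plant contributes exactly one biological data point; construct mean and SEM
(sample sd over biological values / √n) are computed on those. Relative GFP
is the construct mean divided by the Gal4 control mean *of the same plate /
library*; batches are never pooled before normalization. A construct is
called a repressor when relative GFP ≤ 0.5; the boundary is included so the
call is deterministic. Activators (relative GFP > 1) are retained and
flagged, never called repressors. Cross-library scores use the affine map
`(gal4 − x) / (gal4 − srdx)` anchored on the two controls shared by every
library; scores > 1 (stronger than SRDX) and < 0 (activation) are allowed,
and Gal4 mean ≤ SRDX mean is rejected as degenerate controls.

ΔΔCq expression assumes amplification efficiency exactly 2 (no efficiency
calibration): per sample, ΔCq = Cq(target) − Cq(reference), expression =
2^(−ΔCq), rescaled so the wild-type sample mean is exactly 1.

## The synthetic ground truth

The simulator stands in for the wet-lab assay so the whole analysis is
testable end to end. Its model:

- **Planted grams.** A ground truth designates disjoint sets of "strong"
  (repressing) and "weak" (activating) n-grams (lengths 2–4, default 5 of
  each). Every occurrence (counted once per start position, overlaps
  allowed) contributes −e or +e to a motif's net effect; default
  e = 0.3.
- **Link.** Repression strength (fraction of GFP reduction) is a decreasing
  logistic in the net effect, scaled to (−0.6, 1.0) to span the range a
  real screen shows — from ~50% activation to near-complete repression —
  with strength exactly 0 for an unplanted motif. The steepness τ = 0.5 puts
  the 50%-reduction repressor threshold at three net strong occurrences,
  which keeps single-gram effects sub-threshold (realistic: a lone short
  gram rarely makes a strong repressor) while allowing densely planted
  motifs to approach saturation.
- **Library construction.** 84 motifs by default, lengths uniform on 5–16
  aa. Each motif draws independent numbers of strong and weak gram
  insertions (probabilities 0.45/0.20/0.13/0.10/0.07/0.05 for 0–5), fills
  the remaining positions with background residues and shuffles the token
  order; the realised sequence (after truncation to the target length)
  determines the true strength, so partially truncated grams do not count.
  Background residues follow a leucine-rich, D/N/P-elevated composition
  rather than a uniform one — EAR-family motifs are L-rich, and the skew
  gives common background grams realistic token counts. A side effect of
  per-motif dosing is that longer motifs can host more planted grams, so a
  positive length–strength correlation emerges without being imposed.
- **Noise.** Fluorescence is `exp(log baseline + log(1 − strength) + b + t)`
  with Gaussian log-scale plant-level (b) and disk-level (t) terms, i.e.
  multiplicative lognormal noise at both levels (fluorescence is positive
  and heteroskedastic); defaults sd 0.05 each. Strength at the ceiling
  (1.0) is clamped to a configurable fluorescence floor and flagged.
- **Controls.** Gal4 (strength 0, baseline 1000 AU) and SRDX (strength 0.9,
  i.e. at the strong end but beatable) are appended to every assayed
  library; their presence is enforced at simulation time.
- **qPCR.** Cq tables are generated so that a genotype's target-minus-
  reference Cq differs from the wild-type mean by −log2(fold change) plus
  noise.

What the simulator does **not** emulate: Agrobacterium titer and leaf-
position effects, plasmid copy number, plate/edge effects, background
fluorescence, and any real sequence–function biochemistry beyond the planted
grams. Passing tests therefore demonstrate that the analysis recovers the
structure it assumes, not that the biological conclusions transfer to real
data.

## n-gram classification

Grams are tallied per strength quartile of the non-control constructs
(ranked by 1 − relative GFP, ties broken by construct id; remainder
constructs go to the stronger quartiles first). Representation is measured
as within-quartile frequency (count / total gram tokens of the same length
in that quartile) divided by the pooled frequency — a scale-free ratio that
tolerates unequal sequence mass per quartile. Classification: strong iff
ratio(Q1) ≥ 2 and ratio(Q4) < 1; weak iff the mirror image; moderate iff all
four ratios lie in [0.75, 1.25]; anything else (including grams with
undefined ratios from an empty quartile) is unclassified. Counting is
per-occurrence by default, per-construct presence as an option. Note the
rules are deliberately permissive at low counts — a gram seen once, in Q1,
is "strong" — so the strong/weak sets mix genuinely causal grams with
passengers; the evaluation stage measures what that mixture is still worth.
The ±25% moderate band, by contrast, is strict at desk-scale token counts
and can come up empty on some seeds; the pipeline then skips that SynEAR
class and records the skip.

## SynEAR generation

Each requested class draws a target length uniformly from the natural
library's empirical lengths ("strongest" scales the draw by 1.5, rounded,
reflecting the observed length–strength correlation; the factor is
configurable), then concatenates grams drawn uniformly from the class set
(the "strongest" class reuses the strong set) until the target is reached,
truncating the final gram for an exact length. Truncation rather than
rejection guarantees termination. Uniform (not frequency-weighted) gram
sampling is the default. Sequences are unique within a library; a class
whose gram pool is too small to supply the requested number of unique
sequences yields a partial library with an explicit error report, which the
pipeline keeps and records.

## Evaluation

Observed repression (1 − relative GFP, per-construct mean) is binned into
four ordinal classes by three thresholds that maximise agreement with the
predicted classes. The search is exhaustive over all cut positions at
midpoints between consecutive distinct values, including positions outside
the data range and coincident cuts (so degenerate solutions that empty a
class are admissible); ties break toward the lexicographically smallest
threshold triple; coincident cuts are realised as strictly increasing
thresholds by epsilon offsets too small to cross any data point. The
optimum therefore depends only on the ranks of the data, and a brute-force
midpoint search reproduces it exactly.

Two null models contextualise the confusion-matrix accuracy, both with the
thresholds held fixed at the real fit: shuffling the observed labels
(permutation null; its mean has the closed form Σ_c n_pred(c)·n_obs(c)/n²)
and replacing the predictions with uniform random guesses (bootstrap null;
mean 0.25, sd √(0.1875/n) regardless of the observed label distribution).
Each reports the null mean and sd, the percent of null runs the real model
outperformed, an empirical two-tailed p with +1 correction
(2·min((k≥+1)/(N+1), (k≤+1)/(N+1)), capped at 1) and a normal-approximation
two-tailed p — two conventions are reported because no single formula is
canonical for permutation p-values.

## Sequence identity

Global Needleman–Wunsch with match +1, mismatch −1, gap −1 and no free end
gaps; percent identity = identical columns / alignment length × 100 (gap
columns in the denominator — the conservative choice, yielding lower
identities than match-only denominators). Co-optimal alignments can differ
in identical-column count, so the DP tracks, among optimal-score
alignments, the maximum identity count and then the minimum alignment
length; the reported identity is thus deterministic and independent of
traceback order. The DP is written out explicitly for this reason; tests
cross-check its optimal score against Biopython's PairwiseAligner and its
identity against full alignment enumeration on short sequences.

## Statistical components

- Fisher's exact test (scipy): one-sided = upper hypergeometric tail;
  two-sided = minimum-likelihood convention. The enrichment table for
  dual-canonical-motif constructs uses the "stronger half" = top ⌈n/2⌉
  constructs by mean repression, controls excluded, ties by id.
- Dunn's post hoc test is implemented directly (joint ranking, tie
  correction Σ(t³−t)/(12(N−1)), z per pair, Bonferroni = raw p × number of
  comparisons capped at 1); groups with fewer than two values are excluded.
- Spearman's ρ for length vs strength; undefined (reported missing) when
  all lengths are equal.

## Reproducibility and problem sizes

All randomness flows from one seed through `numpy.random.SeedSequence`
substreams, one per pipeline stage, so complete runs are byte-identical
under a fixed seed. Default problem sizes — 84 natural motifs, up to 80
SynEARs, 1000 permutations, 1000 bootstrap runs — were chosen as the scale
at which the evaluation statistics are stable (null means within a few
tenths of a percent) while a full run stays in the seconds range.

## Known limitations

- The moderate-gram band often comes up empty at desk-scale token counts
  (see above); SynEAR libraries then cover three classes.
- The planted-gram ground truth is additive; epistasis between grams,
  position effects and canonical-motif context are not modelled, which is
  precisely why most simulated "strong-class" signal survives gram
  concatenation — real motifs need not behave this way.
- Percent identity conventions differ between tools; the values here are
  comparable within the package, not across methods.
- The repressor fraction of a simulated library depends on the insertion
  dose distribution and is lower than a screen enriched for curated
  candidates would show; the defaults favour a well-separated quartile
  structure over a high repressor yield.
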