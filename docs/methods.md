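# Methods

This note records the exact statistical definitions, the rationale for
the synthetic-benchmark parameters, and the known limitations.

## 1. Scoring model

**PSWM.** Columns are log2 odds of position-specific base frequencies
(pseudocount-regularized) against a background base distribution, then
**consensus-normalized**: each column's maximum is shifted to exactly 0,
so the consensus sequence scores 0 and every other window scores < 0.
Cells are floored at −20. Scanning a region takes, at each window
position, the better of the forward and reverse-complement scores; the
region's `ScoreSample` is the multiset of all window scores from both
strands (`n = 2(L − w + 1)`).

**Composite promoter model.** A sigma70-style scorer: −35 element +
spacer of 15–19 bp (spacer-length weights normalized so the best spacer
contributes 0) + optional extended −10 "TG" dinucleotide + −10 element.
The score at a position is the maximum over spacer lengths of the sum of
the parts; the model behaves like a single PSWM with footprint
`w35 + 19 + wext + w10`.

## 2. Backgrounds

1. **Convergent intergenic** — the pooled window scores of all gaps that
   lie between two genes transcribed toward each other (strand pair
   `+ −`). Such gaps are upstream of nothing, so they are never under
   selection *for* binding sites, while remaining real intergenic DNA
   with genuine composition; under genome-wide negative selection they
   are also depleted of chance high-scoring windows.
2. **Randomized** — windows of order-2 Markov (trinucleotide-preserving)
   sequence sampled to the length profile of the real intergenic
   regions. The model's joint (k+1)-mer probabilities equal the direct
   sliding-window counts exactly; an Altschul–Erickson exact
   k-mer-preserving shuffle is also provided.

Backgrounds carry a `scanner_id`; testing a sample against a background
produced by a different scorer or strand mode raises a warning.

## 3. Tests

**One-sided KS.** With survival functions `S(x) = fraction of scores ≥ x`,

    D = max(0, sup_x [ S_region(x) − S_background(x) ])

with the sup evaluated exactly over the pooled set of observed values
(ties handled exactly), and

    p = min(1, exp(−2 D² n m / (n + m))).

The one-sidedness means only **over**representation of high scores can
be significant; a region depleted of good windows has D = 0, p = 1.

**Anderson–Darling.** The two-sample rank statistic (k-sample AD
restricted to k = 2) with midrank tie correction and exact null
variance; the standardized statistic `Tk = (A2 − mean)/sd` is converted
to a P-value by quadratic interpolation of log-significance across the
published critical values, continued linearly in log-space beyond the
table. Ranking (for ROC) uses the statistic itself, not the P-value. A
one-sample mode (region vs the background ECDF treated as fixed) is
available behind a flag and returns the statistic without a P-value.

**Hybrid.** Regions with KS `p ≥ 0.5` are classified non-target without
running AD (and rank below every AD-stage region); the rest are
classified and ranked by AD. This keeps AD's sensitivity while the
cheap KS filter removes the regions whose "significance" under AD would
come only from background misspecification.

**Permutation oracle.** `permutation_pvalue` pools region and background
scores, re-splits at sizes (n, m) `n_perm` times, and returns
`(1 + #{perm ≥ obs}) / (n_perm + 1)`. It is the calibration reference
for both asymptotic P-values.

**Multiple testing.** The results table reports raw P-values plus a
Benjamini–Hochberg `p_adjusted` column; default classification uses the
raw `P < 0.05`.

## 4. Evaluation

* **Max baseline** — region statistic = best window score; its
  operating threshold is the largest `t` recovering ≥ 98% of the known
  training-site scores (the `ceil(0.98·N)`-th largest score).
* **ROC/AUC** — swept over each method's ranking statistic with the
  target regions as positives and length-matched ORF-interior segments
  (50 bp margins from ORF ends) as putative negatives; ties step
  at once; trapezoidal AUC (equals the Mann–Whitney identity).
* **Threshold metrics** — sensitivity `TP/(TP+FN)`, specificity
  `TN/(TN+FP)`, accuracy `(TP+TN)/(P+N)`; P-value methods hit iff
  `p < 0.05` (strict), Max hits iff `score ≥ t`.
* **Background comparison** — `compare_d_enrichment` applies the same
  one-sided KS to the two sets of per-region D scores.

## 5. Synthetic benchmarks

The generator produces a circular genome of alternating ORFs and
intergenic gaps with random strands, plants sites in a chosen number of
"target" gaps by sampling from the PSWM's probability interpretation
(`strength` interpolating between uniform and the motif distribution),
and can apply **negative selection**: rejection-resampling of any
non-planted window scoring above a threshold, the minimal model of
purifying selection against spurious sites. Region labels are exactly
recoverable by `classify_intergenic` (round-trip tested).

Preset rationale (all frozen before the acceptance tests were written):

* `crp_like` — strong sparse sites (strength 0.85, 2–4 sites in 100 of
  ~260 regions), no negative selection: the regime where even the
  pooled intergenic score distribution shows a visible high-score
  excess over the randomized background.
* `sigma70_like` — weak multi-site targets (strength 0.65, 3–5 sites,
  200 targets), negative selection at −14: individual sites are
  undetectable (the 98%-recovery Max threshold falls below almost every
  region's best window) but the region-level distribution shift is
  detectable — the headline use case.
* `background_contrast` — weak sparse emission (0.55) scored with the
  same sigma70 matrix, 300 targets / 300 negatives, negative selection
  at −14, and GC-58% ORFs. The GC shift makes ORF-interior negatives
  score so low that their D is ≈ 0 under either background, while the
  depletion empties the convergent background's high-score band
  (randomized sequence keeps ~1.1% mass there), boosting the
  (undepleted) positives' D by ≈ +0.03 under the convergent background
  only. The positive/negative separation is then consistently sharper
  under the convergent background. Without the GC shift both sets share
  the chance-tail uplift and the contrast is a coin flip; with much
  deeper depletion the negatives' D re-inflates and the contrast breaks.

## 6. Limitations

* **The KS P-value is conservative.** `exp(−2D²nm/(n+m))` is the
  Hoeffding-type upper bound on the exact one-sided tail probability.
  Measured against a 20,000-permutation oracle at n = 40, m = 400 the
  excess is +0.005 to +0.04 for p ∈ [0.005, 0.9] (factor ≈ 1.1–1.25),
  several binomial standard errors of the oracle; agreement within 3 SE
  holds only for p ≲ 1e−3. The error is one-sided (never
  anti-conservative) and shrinks as ~1/√n. The corresponding property
  test is left failing with a diagnostic message rather than loosened.
* **Overlapping windows are dependent**, so the nominal n overstates
  the information content. In particular, pooling forward and
  reverse-complement scans doubles n while the two strands share the
  region's compositional fluctuations, making the two-strand KS test
  mildly anti-conservative under a region-scan null (~10.7% rejections
  at P < 0.05 vs ~3.5% for forward-only scans and ~1% for iid scores).
  The null-calibration property is therefore stated for forward-strand
  scanning; two-strand P-values should be read as ranking scores more
  than exact error rates (classification thresholds are benchmarked
  against the same pipeline's null).
* **AD P-values below the critical-value table** are a log-space linear
  extrapolation, accurate to order-of-magnitude only; AD *ranking* (the
  statistic) is unaffected.
* The generator makes no attempt to mimic real genome composition,
  operon structure, or binding-site clustering beyond what is described
  above.
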