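# Methods

## The probabilistic clock

For each CpG site k in the reference aging cohort, methylation beta is
regressed on chronological age by ordinary least squares, giving a slope
a_k (beta units per year), an intercept b_k, the Pearson correlation r_k
and the number n_k of complete (age, beta) pairs used. Missing betas are
handled per site: a site is fit on its own complete pairs, and it is
retained only when n_k ≥ 3 and both age and beta have nonzero variance on
those pairs (otherwise slope and correlation are undefined). The fit is a
closed-form vectorized computation over all sites at once; it agrees with a
site-by-site `scipy.stats.linregress` to relative 1e-9 (asserted in the
test suite) and passes through the per-site centroid to 1e-9 absolute.

Given a query profile m over sites S shared with the model, the sites with
the highest |r_k| are selected. Two modes exist:

* **percentile** (default 1%): keep ⌈value/100 · |S|⌉ sites — ceiling, so
  any positive percentile keeps at least one site;
* **fixed_number**: keep min(value, |S|) sites. The helper
  `fixed_number_from_cohort` derives the fixed count as the mean, over a
  cohort of profiles, of the counts percentile mode would use — the
  two-step cutoff used for cell-type-specific profiles, which tend to share
  similar CpG subsets so a common count is comparable across samples.

Ties in |r_k| break by (chromosome, position) ascending; every ranking and
truncation in the package is deterministic.

The epigenetic age is the argmax over a grid (default 0–100 years, step
0.1, 1001 points) of the Bernoulli log-probability
P(A) = Σ_k [m_k log p_k(A) + (1−m_k) log(1−p_k(A))] with
p_k(A) = clamp(a_k·A + b_k, ε, 1−ε). Fractional m_k (aggregated pileup
betas) enter verbatim; no rounding to binary. Grid ties resolve to the
lowest age. The score curve is returned with the estimate so callers can
inspect its shape.

Numerical choices:

* ε = 0.001. Without clamping, a linear prediction leaving [0, 1] would
  produce log of a non-positive number; ε bounds each site's contribution
  at |log ε| ≈ 6.9 nats and keeps every grid value finite. The value
  follows the clamp customarily used in probabilistic single-cell clocks of
  this family.
* Grid ages are rounded to one decimal at construction, so the returned
  estimate is an exact multiple of 0.1.
* `min_sites` (default 1) rejects profiles with too few usable sites; 300
  is the recommended setting for cell-free DNA, where sparser intersections
  make the grid search unreliable.

Site selection is per sample (the intersection differs per profile), so two
profiles of the same person may be scored on different CpG sets; this is a
property of the method, not an implementation accident.

## Marker discovery and the cell-type atlas

Differential methylation between two leukocyte groups (defaults named
"myeloid" and "lymphocyte") is assessed per CpG with four filters, all
configurable:

| filter | default | meaning |
|---|---|---|
| `min_coverage` | 10 | every sample must reach this read depth at the site |
| `min_mean_diff` | 0.4 | minimum \|group mean beta difference\| |
| `max_p` | 0.001 | Welch (unequal-variance) two-sample t-test p-value |
| `quantile_gap` | 0.25 | the (1−q) quantile of the lower group must lie below the q quantile of the higher group |

The defaults are explicit stand-ins chosen to be conservative for
well-separated leukocyte lineages; they are surfaced in the API and CLI
precisely because they are tunable study parameters, not constants of the
method. A Benjamini–Hochberg option exists behind `fdr_bh` (off by default;
the raw-p cutoff is the primary interface). Marker testing is done at the
level of individual CpGs — the atlas the downstream fragment scoring needs
is a per-CpG mean-beta table, so the CpG-level test produces the same
interface a block-segmentation approach would after mapping blocks back to
CpGs. Tightening any threshold can only shrink the marker set
(monotonicity is asserted across threshold ladders in the tests).

## Fragment-to-cell-type assignment

Eligibility: autosomal chromosome (allow-list, default chr1–chr22),
mapping quality ≥ 20, and ≥ 5 CpGs overlapping each cell type's marker set
(with a single shared marker table the per-type checks coincide; they are
still enforced per type in case a column has missing means). The 5-CpG
minimum is the published operating point at which tissue-of-origin
discrimination by this score family exceeds 82% AUROC.

Scoring: L_t = Σ_k (1 − |r_k − c_k,t|) over the overlapping CpGs — a
per-site agreement in [0, 1], so 0 ≤ L ≤ n_overlap. Assignment goes to the
type t with L_t ≥ (1/0.95)·L_s for every other type s; when some L_s = 0
the ratio is undefined and the rule degenerates to requiring L_t > 0. For
two cell types the "all others" and "second best" readings coincide; with
more types the pairwise-all reading is implemented. Fragments failing the
ratio test are "unassigned" and excluded from profiles but counted in the
attrition log.

Aggregation piles assigned fragments per site: coverage = number of
covering fragments, beta = mean call, minimum coverage 1 by default.
`profile_concordance` reports the median absolute per-site deviation
between an aggregated profile and an atlas column, the summary used to
check that a deconvolved profile resembles its own reference more than the
other type's.

## The synthetic generators

`SimulationConfig` fixes the study conditions; all generators are
bit-reproducible under the seed.

* **Reference cohort** — 519 samples by default, ages uniform on 0–100 y,
  per-site slopes uniform on ±0.005 beta/year with a 20% zero-slope
  fraction, betas anchored at mid-age inside (0.15, 0.85) and perturbed by
  Gaussian noise (sd 0.02, truncated to [0, 1]). This emulates array-like
  measurement of a broad, even age distribution: slopes of a few tenths of
  a percent methylation per year and percent-scale noise are the magnitudes
  typical of blood methylation data.
* **Atlas and fragments** — marker means 0.5 ± separation/2 (default
  separation 0.5, i.e. 0.25 vs 0.75; which type is hyper-methylated
  alternates at random), 5 samples per type with within-type sd 0.05,
  null sites with a common mean. Fragment true origins are drawn from a
  75/25 myeloid/lymphocyte mixture; calls are binary Bernoulli draws from
  the true type's marker means at `cpgs_per_read` markers sampled without
  replacement (default 5, the eligibility boundary). An independent 5%
  of fragments is made ineligible (low MAPQ or sex-chromosome placement)
  to exercise the filters; together this mirrors a bulk leukocyte read
  population that is ~75% myeloid with a small unassignable tail.
* **Pileup profiles** — per site, beta is the success fraction of
  `reads_per_site` Bernoulli draws at the model's clamped prediction;
  `exact=True` substitutes the prediction itself (the infinite-depth
  limit used by self-consistency tests).

What the generators do **not** emulate: read-length and fragment-size
distributions, sequencing error and methylation-caller bias, correlated
methylation between neighbouring CpGs, cell-type-specific aging rates, and
batch structure in the reference cohort. Passing tests therefore
demonstrate correctness of the estimators and the filters under the stated
statistical model, not performance on real cohorts.

On mixture recovery: with binary calls at separation 0.5, a fragment's
assignment is effectively a majority vote of its calls, each correct with
probability 0.75. At exactly 5 calls the misassignment rate is
P(Bin(5, 0.25) ≥ 3) ≈ 0.104, which biases the recovered majority fraction
to ≈0.70 regardless of sample size — an intrinsic property of the
operating point, not an estimation error. The mixture-recovery check
therefore uses 10 calls per fragment, the more realistic regime for a
multi-kilobase read crossing a differentially methylated block (expected
recovered fraction ≈0.74); the 5-call boundary case is exercised by the
AUROC check instead.

## Problem sizes

The simulations run at desk scale by design: 2,000 reference CpGs / 519
samples for the clock, 200 markers + 900 null sites for the atlas, and
5,000–10,000 fragments for the deconvolution checks. These sizes put the
Monte-Carlo standard errors comfortably inside the asserted tolerances
(e.g. a binomial sd of ~0.004 on a 10,000-fragment mixture fraction against
a ±0.03 band) while keeping the full suite under a minute.

## Known limitations

* The clock is linear per site; nonlinear methylation–age trajectories are
  outside the model.
* No confidence interval accompanies the age estimate; the score curve is
  exposed instead.
* The ratio rule compares likelihoods, not calibrated posteriors; its
  cutoff (1/0.95) trades recall for assignment precision and is exposed as
  a parameter.
* Reference betas are accepted as-is; probe-level quality filtering
  (detection p-values, cross-reactive probes) is upstream of this package,
  as is the extraction of per-read methylation calls from aligned,
  modification-tagged reads.
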