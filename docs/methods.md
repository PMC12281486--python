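# Methods

## Statistical model

The pipeline treats each DIA protein (or metabolite feature) abundance as
log-normal: all modeling happens on the log2 scale, where condition effects
are additive. Preprocessing follows standard enrichment-proteomics order:

1. **Global median normalization** on raw intensities: each sample is scaled
   by a single factor so its median (over non-missing features) equals the
   median of the per-sample medians. The map is idempotent and equivariant
   under global rescaling. Missing cells stay missing.
2. **log2 transform.** Zeros become missing rather than receiving a
   pseudocount: DIA reports absent precursors as blank cells, so a literal 0
   is a measured value but carries no usable log-abundance, and dropping it
   keeps the paired complete-pair rule well defined. No imputation is
   performed anywhere.

### Differential tests

*Paired Student t* across `replicate_index` for the proteomics arms (probe
replicate *i* shares a culture batch with vehicle replicate *i*), *unpaired
Welch t* for the metabolomics groups. Both are two-sided. Rationale for the
split: the enrichment experiment has an explicit pairing structure; the
group experiment does not, and Welch avoids the equal-variance assumption at
*n* = 5. Both variants are exposed as config switches (`proteomics_paired`,
`metabo_paired`, `*_fdr_method`).

Degenerate cases: all differences exactly zero → p = 1; zero variance with
nonzero mean → p floored at 1e-300 so y = −log10 p stays finite. Features
with fewer than two complete pairs (or fewer than two values per group) are
skipped and counted in the run log, not reported as rows.

### Two-stage step-up FDR

`bky_fdr` implements the adaptive two-stage linear step-up procedure
(Benjamini, Krieger & Yekutieli 2006). Both stages operate at
α′ = α/(1+α): stage 1 is plain BH at α′ and estimates m₀ = m − r₁; stage 2
re-runs BH at α′·m/m₀ (rejecting everything when m₀ = 0, nothing when
r₁ = 0). Rejection sets are verified against an independent implementation
(statsmodels `fdr_tsbky`) in the test suite.

Q-values are defined as the smallest α at which the procedure rejects the
hypothesis. Because the m₀(α) estimate is a non-increasing step function of
α with breakpoints A_r = g(m·u_r), where u_j = min_{i≥j} p_(i)/i and
g(v) = v/(1−v), the q-value of the rank-j p-value has the closed form

    q_j = min_r max(A_r, g(u_j · (m − r))),   r = 0..m,

computed vectorized in O(m²) (chunked to bound memory). This makes q-values
monotone in p-rank and exactly consistent with the rejection flags
(`reject == (q <= alpha)`).

The metabolomics stage defaults to plain BH q-values, with the two-stage
procedure available as an option (`metabo_fdr_method: bky`); the proteomics
stages default to the two-stage procedure.

### Gaussian fit and reciprocal curve

The probe-vs-vehicle fold-change histogram (Freedman–Diaconis bins, minimum
20; override via `n_bins`) is fit by nonlinear least squares to
A·exp(−(x−μ)²/2σ²), initialized at A = max bin count, μ = sample median,
σ = sample sd, parameter tolerance 1e-8. σ is returned as an absolute
value. At least 50 finite fold changes are required for a stable fit; on
non-convergence the fit falls back to a robust σ = 1.4826·MAD and flags
`converged = False`.

The enrichment boundary is the reciprocal curve y > c/(x − x₀) with
c = 0.8 and x₀ = μ̂ + 1·σ̂. Centering the cutoff at μ̂ (not at zero)
protects against a globally offset fold-change distribution. The filter is
one-sided: only the enrichment tail (x > x₀) can pass, and every threshold
in the pipeline is a strict inequality, so boundary points (x = x₀, or
exactly q = 0.05) never pass.

### Specificity call

Stage 2 recomputes the FDR **over the enriched subset only** — the
competition comparison is a follow-up hypothesis family, and restricting the
family matches the sequential logic of the workflow; the global q-values can
be reused instead via `competition_fdr_scope: all`. A feature is `specific`
iff q < 0.05 and probe-over-competition log2 FC > 1 (the enrichment is lost
when the parent compound competes), `nonspecific` if it was enriched but
fails those criteria (including features untestable in the competition
comparison), else `not_enriched`. An optional stage-1 q-gate
(`stage1_q_max`) additionally requires probe-vs-vehicle q below a threshold
before the curve filter; it is off by default since the curve already
combines effect size and significance.

## Metabolomics stage

Pooled-QC filtering removes features whose QC coefficient of variation
(sample sd / mean, on raw intensities, n−1 denominator — conventional at
small n) strictly exceeds 0.25. Process-standard and instrument QA ceilings
(0.20 / 0.10) are carried in the config and `QCReport`. Features whose QC CV
cannot be computed are retained and flagged rather than silently dropped.

Significance filters are conjunctions of optional strict criteria
(p, q, |log2 FC|, annotation level). The fold-change criterion is two-sided
by default (`|log2fc| > threshold`), with a one-sided switch. Metabolite
log2 fold changes are differences of group means of log2 normalized
abundances (zeros treated as missing, consistent with preprocessing).

Clustering uses d = 1 − Pearson r and average (UPGMA) linkage via scipy;
rows are z-scored for display. Trees are compared in tests by cophenetic
distances, which identify UPGMA trees irrespective of merge enumeration
order; scipy's agglomeration is deterministic, with exact ties resolved by
its fixed scan order. A brute-force O(n³) agglomeration is kept in the test
suite as the oracle.

## Synthetic data: what it emulates, and what it does not

`simulate_pal_experiment` draws per-feature baselines from
N(20, 2²) log2 units (typical DIA intensity spread), adds a shared
per-(feature, replicate) offset of sd 0.1 — this induces the within-pair
correlation that the paired t-test exploits — and per-cell noise of sd 0.4.
Spiked binders get +2.5 log2 in the probe arm; specific spikes lose the full
2.5 under competition, nonspecific spikes keep it. Missingness is uniform
(MCAR) at 5%, a typical DIA missing-cell rate after match-between-runs. The
defaults (3,000 features, *n* = 8, 10 + 10 spikes) mirror the experimental
design the pipeline targets.

`simulate_metabolomics` uses three biological groups of five plus five
pooled-QC injections; affected features shift +3 log2 in the enzyme
overexpression group; each feature's QC replicates receive a technical CV
drawn uniformly from (0.02, 0.30), so roughly one in six features violates
the 25% QC rule — matching the typical fraction of unstable features in
untargeted data. Annotation levels are assigned multinomially
(L1/L2/L3/unannotated = 0.10/0.20/0.30/0.40), independently of effect
status.

What the generators do **not** model: intensity-dependent (MNAR)
missingness (available as a config extension point but off by default so
recovery benchmarks are stable), batch/run-order drift, correlated features
(pathway structure), peptide-level roll-up noise, and retention-time or m/z
artifacts. Passing the recovery benchmarks therefore demonstrates that the
decision procedure is correct and well calibrated under its own model
assumptions — not that real acquisitions are free of the confounders above.

## Problem sizes used in tests and the acceptance script

Monte-Carlo checks run at the default generator settings: 50 seeds for the
end-to-end spike-recovery and null-calibration benchmarks, 200 repetitions
for the FDR calibration (5,000 features, 90% true nulls, +1.5 log2 effects,
0.5 noise sd, 8 pairs), 20 seeds × 10,000 draws for σ recovery, and 500
random p-vectors for the step-up cross-check. These sizes give Monte-Carlo
standard errors comfortably below the asserted margins.

## Known limitations

- The curve filter's selectivity depends on the Gaussian fit; heavy-tailed
  or strongly bimodal fold-change distributions can inflate σ̂ and hide weak
  binders. The fit diagnostics (rss, converged, n_bins) are reported for
  auditing.
- With very small enriched subsets (< ~5 features), the stage-2 FDR has
  little resolution; the `competition_fdr_scope: all` option trades family
  logic for stability there.
- No moderated (empirical-Bayes) variance estimation: at n = 8 pairs the
  plain paired t is adequate, but at smaller n a moderated test would be
  more powerful; this is deliberately out of scope.
- Clustering requires complete rows; features with missing values among the
  clustered samples are dropped from the heatmap stage rather than imputed.
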