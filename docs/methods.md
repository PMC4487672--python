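# Methods

## Problem setting

Given gene-level log2 expression matrices from one or more case/control
studies, the package identifies gene pairs whose co-expression differs
between the two conditions and characterizes the resulting network.  The
design principle is redundancy: four scoring engines with different failure
modes each produce a ranked candidate list, and only pairs ranked
consistently well across engines survive the merge.

## Preprocessing and DE calling

Studies are merged by per-gene, per-study z-score normalization,
`Y = (X − X̄_ik)/σ_ik` with the sample (n−1) standard deviation, which
removes additive study batch offsets exactly (per study each gene has mean
0, sd 1 after the transform).  The gene universe is the intersection of the
studies' gene sets, because the z-score needs per-study values for every
gene; genes with zero within-study variance are dropped with a warning.

Fold changes cannot be read off z-scores (the per-gene rescaling destroys
log2 units), so a parallel matrix is kept that is only *centered* per gene
per study.  `detect_de` computes the log2 fold change on that matrix and
the t-statistic on the z-scored one.  The moderated t shrinks the pooled
within-group variances toward a common prior estimated by moment matching
on the log variances: with `e_g = log(s_g²) − ψ(d/2) + log(d/2)`, the prior
degrees of freedom solve `ψ′(d₀/2) = var(e) − ψ′(d/2)` (trigamma inversion
by bracketed root-finding) and the prior scale follows from the mean of
`e`.  Posterior variances are `(d₀s₀² + d s_g²)/(d₀ + d)` and the t
reference has `d₀ + d` degrees of freedom.  A plain Welch t is available
via `use_moderated=False`.  A gene is DE when `p < 0.05` and
`|log2FC| > 2` (both thresholds configurable); BH-adjusted p-values are
reported alongside.

Quantile normalization (`quantile_normalize`) is provided for inputs that
arrive on incomparable scales: every column is mapped to the row means of
the column-wise order statistics, with ties receiving the average of the
tied quantile means.  Note the tie rule means tied inputs do not land
exactly on the reference multiset — the standard behavior of the
average-tie dialect.

## The four pair-scoring engines

**Database backbone.**  A STRING-style links file (either [0,1] or the
0–1000 integer dialect, auto-detected) is restricted to DE-gene pairs.
Channels are combined as `1 − ∏(1 − Sᵢ)` (no organism-prior correction);
the pair strength is the co-expression channel subscore, with the combined
score kept for reference.  Everything is file-based; no network access.

**Pearson ΔR.**  For all m(m−1)/2 DE-gene pairs, Pearson correlations are
computed within cases and within controls (optionally on within-condition
ranks), with p-values from the t transform with n−2 df.  Half-thresholding
keeps a pair when at least one condition's correlation has BH q < 0.05;
`full_threshold=True` requires both.  The retained strength is
`|r_case − r_control| ∈ [0, 2]`.  The mean absolute correlation
`(|r₁|+|r₂|)/2` is computed and emitted but not used for selection.

**Empirical Bayes.**  Condition-wise biweight midcorrelations (Tukey
biweight around the median, 9×MAD window; Pearson fallback with a warning
when MAD = 0) fill the p×K matrix D.  Correlations are Fisher
z-transformed before mixture modeling — a normal mixture on the bounded
correlation scale is misspecified near ±1.  Initialization fits Gaussian
mixtures with 1..3 components (seeded k-means inside scikit-learn's
`GaussianMixture`) and picks the component count by BIC.  Patterns are set
partitions of the condition indices: the single-block partition is the
equivalent-co-expression (EC) pattern; all others are differential (DC).
Within a block all columns share one latent component; across blocks the
components are *distinct*, with the joint assignment prior proportional to
the product of component weights renormalized over distinct tuples.  The
distinctness constraint is what makes the DC pattern identifiable under a
discrete mixture — with independent assignments the DC pattern would also
absorb same-component draws (probability Σw²) and the fitted DC prior
weight would be inflated by roughly that factor.  EM refines component
means/sds and pattern priors; component weights stay at their initialized
values because they enter the distinct-tuple normalizer, and holding them
fixed keeps the M-step closed-form and the observed-data log-likelihood
provably non-decreasing.  Variants: `zero-step` (posteriors at the initial
estimates), `one-step` (single update; the default, matching common
practice of trusting the initial hyperparameter estimates), `full`
(to ΔLL < 1e−6 or 500 iterations).  `crit_fun` returns the smallest
posterior cutoff whose called set has mean(1 − posterior) ≤ 0.05,
considering only cutoffs at posterior tie-group boundaries so the called
set is exactly `{pp ≥ c}`; control of the posterior expected FDR is
asserted on every run.

**WGCNA weights.**  Similarity `|cor|` (unsigned) or `(1+cor)/2` (signed);
signum hard threshold or soft power adjacency (β default 6, the unsigned
convention; an optional scale-free-fit helper suggests β); standard
topological overlap with `ω = 0` for fully disconnected pairs and a zero
diagonal (module detection is out of scope, so the diagonal is never
consumed).  The pair strength is the soft adjacency by default (TOM via
flag).  A differential variant scores `|a_case − a_control|` from
condition-specific similarities.

## Rank-product merge and PFP q-values

Within each method, pairs are ranked by strength descending with average
ties, giving rank ratios in (0, 1]; the candidate universe is the union of
the methods' lists (a `min_methods` option can require ≥ 2).  The rank
product multiplies the per-method ratios with exponents λᵢ (default 1; a
smaller λ flattens a dominant method's contribution toward 1, per-method
values are configurable).  The null distribution reassigns each method's
observed rank ratios uniformly at random over that method's own candidates
— preserving every pair's missing-method pattern — B times (default
500–1000), and `E(RP_g)` is the count of null RP values ≤ RP_g divided by
B.  `q_g = E(RP_g)/rank(g)` is monotonized by a running maximum along
increasing RP so the accepted set is the contiguous prefix with
`q < 0.1`.

A property worth knowing: if an engine's candidate list contains almost
only true pairs (as happens for the posterior-FDR-controlled EB list on
strongly planted data), its within-list ranks carry no signal and the
permutation null matches the observed ranking, so that engine contributes
nothing to the merge.  The merge discriminates best when at least one
engine supplies a broad ranked list in which true pairs sit near the top.
This is why the end-to-end pipeline takes the WGCNA engine's top 25% of
differential weights (~200 pairs at 40 genes) rather than a high absolute
cutoff.

## Network analysis

Accepted pairs form an undirected simple graph.  Hubs are nodes with
degree at or above the 90% empirical quantile (linear interpolation,
inclusive ≥).  EASE enrichment builds, per gene set, the 2×2 table over a
caller-supplied background and computes the hypergeometric upper tail with
the jackknifed overlap `a = max(a′ − 1, 0)`; a set passes at EASE < 0.01
with more than 2 list genes.  The EASE score is never smaller than the
plain Fisher p and equals 1 whenever `a′ ≤ 1`.  NEA counts edges with one
endpoint in the altered set and the other in the functional set (an edge
inside the intersection counts once; the statistic is symmetric in the two
sets) and compares against R ≥ 20 randomized networks, each produced by
10×|edges| double-edge-swap *attempts* from the observed graph — proposals
creating self-loops or duplicate edges are rejected, so fully constrained
graphs return unchanged and degree sequences are preserved exactly (checked
after every sample).  The empirical p uses the add-one estimator
`(1 + #{null ≥ obs})/(R + 1)` to avoid p = 0 at finite R.  Per-patient
difference profiles (`log(T/N) − ave(log(T/N))`) are provided for building
patient-specific altered gene sets.

## Synthetic data

The simulator emits log2-scale matrices directly (the pipeline's entry
point is the gene-level matrix): per-gene baselines ~ N(8, 2²), unit
noise, per-study per-gene batch offsets ~ N(0, batch_shift_sd²), a
de_log2fc mean shift in cases for the DE genes, and DC pairs built from a
shared latent factor `x = √|r|·z + √(1−|r|)·ε` (sign on one member), which
hits the target correlation exactly in expectation.  Planted pairs use
disjoint DE genes.  One root seed drives everything; per-study streams are
spawned deterministically, so identical configurations are bit-identical.
Defaults describe the standard planted scenario used across the tests: 200
genes, two studies of 30+30 samples, 40 DE genes at 4 log2 units against
unit noise, 10 DC pairs with r_case = 0.9 vs r_control = 0 — strong,
clean signal chosen so that recovery failures indicate implementation
defects rather than statistical bad luck.  The synthetic STRING table
emulates a curated database covering the true pairs (co-expression
subscore U(0.6, 0.95)) plus 30 weaker background edges among DE genes
(U(0.15, 0.5)), roughly one edge per gene.

What the simulator does **not** emulate: probe-level effects, heavy-tailed
or count noise, correlated gene modules beyond the planted pairs,
nonlinear dependence, confounded designs, or missing values.  Passing
tests therefore demonstrate correctness of the computations and
calibration under the stated model, not performance on real microarray
data.

## Numerical choices and problem sizes

Component sds floored at 1e−3; mixture densities floored at 1e−300;
correlations clipped to ±(1 − 1e−6) before arctanh; trigamma inversion by
`brentq` on [1e−8, 1e8]; average ranks for ties throughout; permutation
count B ≥ 100 enforced (tests and the acceptance script use 300–1000);
EB recovery runs use p = 5000 pairs; end-to-end evaluations average 10
simulated replicates; NEA nulls use R = 150–600 samples.  These sizes keep
the default test suite and the acceptance script fast while leaving the
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The rank-product merge assumes per-method ranks are exchangeable under
  the null; engines whose candidate lists are already purified (see above)
  dilute rather than sharpen the merge.
- The EB model fixes component weights after initialization; if the
  initial mixture fit is poor the EM cannot fully repair it (the BIC
  selection over 1..3 components makes this rare in practice).
- PFP q-values are conservative estimates, not exact FDRs; the accepted
  count on null data is bounded by, not equal to, the nominal level.
- K > 2 conditions are supported through set-partition patterns, but the
  number of patterns (Bell number) and distinct component tuples grows
  quickly; the intended use is the two-condition case.
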