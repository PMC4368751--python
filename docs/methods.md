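# Methods

## Model

Signalling entropy treats a sample's transcriptome as weights on a random
walk over a protein interaction network (PIN). Log-normalised expression
`E_j > 0` is taken as a rough proxy for protein concentration, and a
simplified mass-action principle — reaction rates proportional to the
product of the active masses — yields the sample-specific stochastic
matrix `p_ij = E_j / Σ_{k∈N(i)} E_k` over the network's edges. The local
entropy `S_i = −Σ_j p_ij log p_ij` measures how evenly protein *i*
distributes its interaction flux; the entropy rate `S̃_R = Σ_i π_i S_i`
aggregates the local entropies over the walk's stationary distribution and
is reported normalised, `S_R = S̃_R / M_R`, where `M_R` is the maximum
entropy rate the topology admits.

Assumptions the model inherits and the package enforces:

* **Graph structure.** The walk requires an irreducible aperiodic chain,
  i.e. a connected, non-bipartite network. `interactome.restrict_and_validate`
  drops unmeasured genes, keeps the largest connected component and
  rejects bipartite components with an explicit two-colouring witness.
  Components below 3 nodes are rejected as degenerate.
* **Positivity.** All expression values must be finite and strictly
  positive — the stochastic matrix and the closed-form stationary
  distribution are undefined otherwise. The package never imputes:
  `offset_normalise(raw, eps)` (`log(raw + eps)`) exists for explicit use
  on raw non-negative intensities, but nothing calls it implicitly.
* **Undirected binary interactome.** Confidence-weighted or directed
  networks are out of scope.

### Stationary distribution: closed form first

Because `p_ij ∝ E_j` on an undirected graph, the chain satisfies detailed
balance with `π_i ∝ E_i D_i`, `D_i = Σ_{k∈N(i)} E_k` (then
`π_i p_ij ∝ E_i E_j`, symmetric). The closed form is exact and O(edges),
so it is the primary computation; the package then verifies `πP = π` to
1e−10 and raises an internal-consistency error on violation — that check
converts silent precondition breakage (e.g. a disconnected graph slipping
through) into a loud failure. The dense/Lanczos left-eigenvector route is
used only as a test oracle.

### Maximum entropy rate

`M_R` is computed constructively as the entropy rate of the
maximal-entropy random walk `p_ij = A_ij ν_j/(λ ν_i)` with stationary
distribution `ν_i²`, where `(λ, ν)` is the dominant eigenpair of the
adjacency matrix, and cross-checked against the identity `M_R = log λ` to
1e−8. The eigenpair uses a dense symmetric solve below 500 nodes and ARPACK
(all-ones start vector, tolerance 1e−10, ≤ 10 000 iterations) above, so
results are reproducible across runs. Natural logarithms are used
throughout; the normalisation cancels the base. `0·log 0 := 0` by
continuity. Normalised entropies that exceed 1 by ≤ 1e−9 (round-off on
entropy-maximal profiles) are clamped to 1; larger excursions raise.

## Mixtures and super-additivity

Mixtures default to the log-expression domain, `(x+y)/2`, where the
super-additivity statement lives; `mode="linear"`
(`log((e^x + e^y)/2)`) emulates physically mixing cell populations. The
super-additivity verdict uses a strictness tolerance of 1e−12 — identical
profiles are classified "equal", never "superadditive".

The panel-level Wilcoxon comparison supports two pairings. The default,
`per_profile`, pairs each homogeneous profile's entropy with the mean
entropy of the mixtures involving it (m differences for m profiles),
matching a per-tissue presentation; `per_pair` pairs each mixture with the
mean of its two constituents (m(m−1)/2 differences). Both are exposed
because the aggregation level is a genuine design choice; per-profile is
the more conservative default. The signed-rank p-value is exact
(enumeration) for n ≤ 25 without ties in |d| and a normal approximation
with continuity correction otherwise; the reported statistic V is the
positive-rank sum (R convention).

The sign expression `sign(1 − 1/b + 2/a) + sign(1 − a + 2b)` is exposed as
a standalone evaluator with `sign(0) := 0` (codomain exactly {−2, 0, 2})
plus a grid driver over `a, b ∈ [0.01, 20]`; the mapping from a concrete
profile pair to `(a, b)` is part of the analytic derivation of the
condition and outside this package's scope.

## SE score and signature derivation

`se_score` is the two-sample t-statistic comparing a sample's z-scored
values over the positively entropy-correlated genes against the negatively
correlated ones. Welch (unequal variance) is the default because derived
signatures are typically very unbalanced (tens vs a handful of genes);
`equal_var=True` gives the pooled variant for sensitivity analysis.
z-normalisation is per gene across samples with ddof = 1; zero-variance
genes are excluded and reported. Signature genes absent from a matrix are
dropped with a warning (cross-platform reality), but at least 2 genes per
set must remain.

Derivation pipeline, with α = 0.05 throughout (exposed as a parameter):

1. **Prognostic screen** — per gene, Cox proportional hazards of
   horizon-censored survival on the gene plus covariates; keep Wald
   p < α for the gene's own coefficient. Non-converging fits are skipped
   and logged.
2. **Entropy-correlation screen** — per gene, Pearson correlation of
   residuals after linearly adjusting both gene and entropy for the
   covariates (categoricals one-hot coded); p from the t distribution with
   n − q − 2 df. Linear residualisation is the simplest defensible
   operationalisation of "independently of" and is pinned as the package's
   choice.
3. **Backward refinement** — joint Cox model on the intersection of the
   two screens; iteratively delete the gene with the largest Wald p ≥ α
   until all survivors are independently prognostic or one gene remains.
   If the unpenalised joint fit diverges (collinearity), it is retried
   with a ridge penalty of 1e−4 and a logged notice.
4. Survivors are split by their correlation sign into the positive and
   negative sets; thresholds, covariates, horizon and intermediate counts
   are recorded in the signature's provenance.

`overlap_resampling_test` quantifies signature stability between cohorts:
Monte-Carlo resampling of size-matched gene sets from the universe,
`p = (1 + #{overlap ≥ observed}) / (B + 1)`; it agrees with the exact
hypergeometric tail within Monte-Carlo error.

## Survival statistics

* **Censoring** at a horizon (5 y breast-style, 3 y lung-style analyses)
  replaces later times by the horizon with event := 0.
* **Cox fits** maximise the Breslow-ties partial likelihood (Newton-
  Raphson via statsmodels, tolerance 1e−8, ≤ 100 iterations); Efron ties
  are available behind a flag. Monotone likelihood (separation) is
  detected via runaway coefficients (|β| > 30) or absurd Wald SEs and
  raised as a convergence error rather than returned as a fit. The ridge
  fallback is a small penalised Newton loop on the same score/hessian,
  with SEs from the penalised information matrix.
* **Concordance index** uses the standard censoring comparability (the
  smaller time must be an event; tied times incomparable), counts score
  ties 0.5, and is oriented so higher score = higher risk (an `--invert`
  CLI flag flips a protective score). It is computed by vectorised
  exhaustive pair enumeration — exact by construction. CIs are
  nonparametric bootstrap percentiles (B ≥ 100 enforced; degenerate
  resamples redrawn, ≤ 10B attempts); bootstrap is used because no
  analytic SE is assumption-free under censoring.
* **Tertiles** cut at the empirical 1/3 and 2/3 quantiles (linear,
  "type 7" convention) with boundary ties assigned to the lower group —
  pinned so stratification is deterministic across implementations.
* **Meta-analysis** is DerSimonian–Laird: Q statistic, 
  `τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw))` with `w = 1/SE²`, pooled
  estimate weighted by `1/(SE² + τ²)`, two-sided z test.
* **Fisher's combined test**: `X = −2 Σ log p ~ χ²(2k)`; p = 0 inputs are
  rejected (floor at machine epsilon upstream if needed).
* **Score comparison** (`compare_scores_meta`) is a paired bootstrap of
  c-index differences per cohort (shared resample indices), pooled by the
  random-effects model — an explicit operationalisation choice, since no
  standard method exists for cross-cohort score comparisons.

## Synthetic data

The generator provides the three inputs the analyses need, deterministic
under an integer seed (numpy `default_rng` seeded with `(seed, stream)`
tuples so the network, tissue and cohort streams are independent).

* **Network**: Barabási–Albert (default, n = 2000 genes, m = 3) or
  Erdős–Rényi; largest component kept, one triangle-closing edge added in
  the rare bipartite case, then passed through the same validation as user
  input. Scale-free degree structure mimics real interactomes' hubs.
* **Tissue panel**: 33 profiles, each with a 50-gene active module grown
  breadth-first from a random seed gene (the BFS may traverse, but not
  claim, genes owned by other modules, so disjoint packing succeeds at
  high occupancy). Module genes get 8.0, background 2.0 — a log2-
  microarray-like scale — with Gaussian noise (sd 0.5) truncated below at
  baseline/10 to preserve positivity without rejection sampling (which
  would break seed determinism). Disjoint strongly-expressed modules are
  the regime in which distinct cell types have non-overlapping active
  pathways, the condition under which mixtures are super-additive.
* **Cohorts**: exponential proportional-hazards event times with log-hazard
  `Σ_j β sign_j g_j + effect·covariate` over k planted, mutually
  independent standard-normal genes (default 5 positive + 3 negative,
  |β| = 1, a binary covariate with log-HR 0.3), and independent
  exponential censoring whose intensity is solved by root-finding to hit
  the target censoring fraction (default 0.3) in expectation. The latent
  heterogeneity score returned as the entropy stand-in is the signed,
  unit-variance average of the planted genes plus N(0, 0.5²) noise, so
  planted genes are simultaneously prognostic and entropy-correlated.
  Planting independent per-gene effects (rather than one shared latent
  driving all genes) is deliberate: it makes each gene *independently*
  prognostic, which is what the backward-refinement step selects for.
  A separate two-group generator plants a known hazard ratio between
  equal-sized groups for hazard-ratio recovery experiments. Every
  generated cohort ships a manifest naming the planted genes, signs and
  coefficients.

What the generator does **not** emulate: platform-specific noise (probe
effects, batch structure), gene–gene co-expression beyond the planted
signals, non-proportional hazards, informative censoring, and the
correlation structure a real interactome induces between expression and
topology. Passing tests therefore demonstrate correctness of the
algorithms and recoverability under the stated model, not clinical
performance on real cohorts.

## Problem sizes

Default experiment scales were chosen to keep desk-scale runs fast while
preserving the phenomenology: the 2000-gene network with 33 × 50-gene
modules reproduces the full 528-pair mixture experiment in seconds;
signature recovery uses n = 300 samples × 100 genes; hazard-ratio coverage
uses 100 replicate cohorts of n = 600; null calibrations use 500
replicates. All are ordinary laptop workloads.

## Known limitations

* The closed-form stationary distribution is specific to the mass-action
  weighting; other edge weightings would need the eigenvector path.
* Wald inference in small cohorts with few events is approximate; the
  per-gene screen warns below 10 events.
* The exact signed-rank null is not computed in the presence of ties in
  |d| (midranks + normal approximation are used instead).
* `derive_signature` inherits the instability of stepwise selection;
  provenance records counts at each stage so users can audit shrinkage.
* Real-cohort headline quantities (meta-analysed c-indices, published
  gene lists) require the original clinical datasets and are outside the
  package's remit; the synthetic experiments validate machinery, not
  clinical claims.
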