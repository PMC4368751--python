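# sigentropy

Signalling entropy of transcriptomes on a protein interaction network.

Bulk tumour expression profiles hide two clinically important quantities
that are hard to assay directly: the stemness of the constituent cells and
the heterogeneity of the cell population. Both manifest as *promiscuous
signalling* — many pathways active at once — and signalling entropy
quantifies exactly that from a single sample's genome-wide expression
profile integrated with an interactome. `sigentropy` is a library and CLI
for computational biologists who want to compute this measure, study its
mixture behaviour, distil it into a compact prognostic gene score, and
evaluate that score on censored survival data.

## The measure

Given an undirected, connected, non-bipartite protein interaction network
with adjacency matrix `A` and a strictly positive log-normalised expression
profile `E`, mass action defines a sample-specific random walk

    p_ij = E_j / Σ_{k∈N(i)} E_k        for j a neighbour of i,

with local entropy `S_i = −Σ_j p_ij log p_ij` and entropy rate

    S̃_R = Σ_i π_i S_i,

where `π` is the stationary distribution of `P`. Detailed balance gives `π`
in closed form, `π_i ∝ E_i · Σ_{k∈N(i)} E_k`, which the package uses as the
primary path (the eigenvector definition is checked internally). The
headline statistic is the normalised signalling entropy

    S_R = S̃_R / M_R,      M_R = log λ_max(A),

where `M_R`, the maximum entropy rate the topology admits, is attained by
the maximal-entropy random walk built from the dominant eigenpair of `A`.
`S_R ∈ (0, 1]` is dimensionless and scale-invariant in `E`.

Two further layers build on the measure:

* **Mixtures** — signalling entropy is *super-additive* at a profile pair
  `(x, y)` when `S_R((x+y)/2) > (S_R(x)+S_R(y))/2`; when that holds across
  a panel, in-silico mixed samples are more entropic than homogeneous ones
  on average, making `S_R` a correlate of intra-sample heterogeneity.
  The package enumerates all pairwise 50:50 mixtures, classifies each
  pair, and summarises the panel with a paired two-tailed Wilcoxon
  signed-rank test, plus the analytic sign-condition certificate
  `sign(1 − 1/b + 2/a) + sign(1 − a + 2b)` (value 2 ⇒ super-additive).
* **SE score** — a compact surrogate: per sample, the Welch t-statistic
  contrasting genes positively vs negatively correlated with signalling
  entropy, on z-scored expression. Signatures are derived by entropy-guided
  feature selection (per-gene Cox screen adjusted for clinical covariates ∩
  partial-correlation screen against entropy, refined by backward
  elimination in a joint Cox model) and evaluated with the usual survival
  machinery: concordance index with bootstrap CIs, tertile hazard ratios,
  DerSimonian–Laird random-effects meta-analysis and Fisher's combined
  test.

## Worked example

```python
import pandas as pd
from sigentropy import restrict_and_validate, signalling_entropy
from sigentropy.mixtures import pairwise_sweep
from sigentropy.synthetic import make_network, make_tissue_profiles

# a triangle network with expression (1, 2, 3)
net = restrict_and_validate({("g1", "g2"), ("g2", "g3"), ("g1", "g3")})
res = signalling_entropy(net, pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0}))
print(f"entropy rate      = {res.entropy_rate:.6f} nats")
print(f"max entropy rate  = {res.max_entropy_rate:.6f} nats")
print(f"normalised SR     = {res.normalised_entropy:.6f}")

# 33 synthetic tissues with disjoint active modules: all 528 pairwise
# mixtures are strictly super-additive
graph = make_network(seed=1)
profiles = make_tissue_profiles(graph, seed=1)
sweep = pairwise_sweep(graph, profiles)
print(f"pairs             = {sweep.n_pairs}")
print(f"superadditive     = {sweep.fraction_superadditive:.0%}")
print(f"wilcoxon p        = {sweep.wilcoxon_p:.2e}")
```

prints

```
entropy rate      = 0.617835 nats
max entropy rate  = 0.693147 nats
normalised SR     = 0.891347
pairs             = 528
superadditive     = 100%
wilcoxon p        = 1.30e-05
```

The triangle numbers are exact: the walk's stationary distribution is
(5/22, 8/22, 9/22), the entropy rate 0.617835 nats, and dividing by the
maximum rate log 2 gives S_R ≈ 0.8913 — an asymmetric expression pattern
keeps the sample below the entropy ceiling, which the constant profile
would attain (S_R = 1). The sweep shows the heterogeneity phenomenology:
every mixture of two distinct "tissues" is more entropic than the average
of its constituents, and the elevation is significant across the panel.

The same workflows are available from the shell via the `sigentropy` CLI
(`entropy`, `mixtures`, `score`, `derive`, `evaluate`, `simulate`
subcommands); run `sigentropy --help`.

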