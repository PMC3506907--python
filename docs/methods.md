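# Methods

## Scope

`grnbench` evaluates gene-regulatory-network inference (GRNI) methods
under controlled, fully synthetic conditions: a generative network model
with Hill-kinetics steady states stands in for real benchmark generators,
so that every claim the pipeline makes (which data design is informative,
how density hurts inference, whether supervision helps, whether regulator
switches between conditions are detectable) is checked against a known
ground truth.

## The generative model

### Networks

`generate_source_network` draws a directed TF→target network with a fixed
TF fraction (`ceil(tf_fraction · n_nodes)` regulators). Edge regulators
are drawn either uniformly (`erdos_renyi`) or preferentially by current
out-degree (`scale_free`), which produces hub TFs; targets are uniform.
Edge count is `round(mean_degree · n_nodes)`; a few bridge edges may be
added to enforce weak connectivity. Signs are activating with probability
2/3 — a rough nod to the activator bias of curated transcriptional
networks.

Networks are **acyclic by default**. Curated transcriptional networks are
predominantly feed-forward, and acyclicity guarantees a unique stable
steady state for the kinetics below. With `acyclic=False`, feedback loops
are allowed; steep negative-feedback loops then oscillate (they have no
stable fixed point at all), and the steady-state solver raises an explicit
non-convergence error naming a directed cycle — that error path is part of
the contract, not a bug.

`sample_subnetwork` grows an induced subgraph by seeded neighbour addition
from a random start node (restarting from a fresh node if growth stalls),
so subnetworks of a denser source are themselves denser at equal node
count — the property that drives the density-vs-accuracy comparison.

### Kinetics

Each gene carries a basal activity b ∈ (0, 1]; each edge a Hill
coefficient n ∈ [1, 10] and half-saturation constant K ∈ (0, 1), sampled
uniformly from configurable ranges (defaults: b ∈ [0.2, 1], n ∈ [1, 10],
K ∈ [0.2, 0.8]). The steady state solves

x_i = min(1, m_i · b_i · Π_activators (ℓ + (1−ℓ)·A(x_a)) · Π_repressors (ℓ + (1−ℓ)·R(x_r)))

with A(x) = xⁿ/(Kⁿ + xⁿ), R(x) = Kⁿ/(Kⁿ + xⁿ), leak ℓ = 0.1 by default.
A(K) = R(K) = 1/2 exactly. Unregulated genes sit at m·b; clamped genes are
fixed.

Numerics: damped synchronous fixed-point iteration, x ← (1−d)F(x) + d·x
with d = 0.5, tolerance 1e-8 on the **undamped** residual |F(x) − x|
(strictly stronger than a step-size criterion, and independent of d),
up to 5000 iterations, all samples of an experiment solved as one matrix.
Samples that fail are retried once at d = 0.9 with a larger iteration
budget: for a local Jacobian eigenvalue λ the damped map contracts when
|d + (1−d)λ| < 1, so d = 0.9 stabilizes oscillatory modes with |λ| up to
19, comfortably above the steepest Hill slope the defaults admit
(≈ n/(4K) ≈ 12.5); slow modes near +1 then just need more, cheap,
iterations. Anything still unconverged raises with a cycle hint.

### Experiment designs

* **wildtype** — one unperturbed steady state.
* **knockdown** — one wild-type sample plus one sample per gene with that
  gene clamped to 0.01 (n_genes + 1 samples). The clamp is a small
  positive value rather than zero so log-scale noise stays defined; it is
  configurable.
* **multifactorial** — each of n samples multiplies every gene's basal
  activity by an independent exp(N(0, τ²)) draw, τ = 0.5 by default. This
  emulates a cohort in which every sample is a different individual with
  its own mild global perturbation.

After solving, multiplicative lognormal measurement noise
(σ = 0.05 by default) is applied and values are clipped to [0, 1]. All
randomness flows from the single seed; datasets are bitwise reproducible.

What the generator does **not** emulate: time-course dynamics, microRNA or
chromatin regulation, combinatorial (AND/OR) logic beyond independent
multiplicative terms, tumor heterogeneity, and platform-specific
measurement artifacts. Passing benchmarks here therefore demonstrate
correct algorithmic behaviour and relative method ordering under this
model — not performance on any particular real dataset.

### Condition pairs with planted switches

`make_condition_pair` derives two models that differ only in planted
regulator switches: groups of targets regulated by exactly one TF (and not
themselves TFs, keeping the expression signature clean) have that edge
reassigned to a different TF in condition B, kinetic parameters carried
over. The manifest of (old TF, new TF, target set) triples is the ground
truth for switch detection.

## MI substrate

Expression is discretized per gene (equal width over the gene's range,
equal frequency by quantile cut points with ties to the lower bin) or over
the global matrix range (global equal width); the last bin is
right-closed. Entropies (in nats — unit choice is free and natural logs
compose with scipy conventions) come from four histogram estimators:

* `empirical` — plug-in −Σ p̂ ln p̂;
* `mm` — Miller–Madow, plug-in + (m̂−1)/(2n) with m̂ occupied bins;
* `shrink` — plug-in on James–Stein-shrunk frequencies toward uniform
  1/m, intensity λ = (1 − Σp̂²)/((n−1)·Σ(1/m − p̂)²) clipped to [0, 1];
* `sg` — plug-in on pseudocount frequencies (nᵢ + 1/m)/(n + 1), the
  Schürmann–Grassberger Dirichlet prior; the full Bayesian posterior
  entropy is out of scope.

MI(X;Y) = H(X) + H(Y) − H(X,Y) on the marginal and joint histograms, with
negative corrected-estimator values clipped to 0. Which bin-boundary and
tie conventions the classic R implementations used is not documented
consistently; the conventions above are fixed, tested, and a plausible
source of small AUC differences relative to other implementations.

## Inference methods

* **rn** — scores are the MI values themselves.
* **clr** — z = max(0, (MI − μ_row)/σ_row) per row (σ the population SD,
  zero rows score 0), combined as sqrt(z_i² + z_j²).
* **aracne** — for every triangle with three positive MI values, the edge
  with MI < min(other two) − eps is marked; marks are computed on the
  original matrix and applied afterwards (non-cascading variant; the
  published description is ambiguous and the non-cascading reading keeps
  the output independent of processing order). eps defaults to 0.
* **mrnet** — per target, greedy forward selection maximizing
  u = relevance − mean redundancy against the selected set, stopping at
  u ≤ 0; the directional score is u at selection time and the symmetric
  score the max of the two directions (the collapse rule is a
  convention; max preserves the stronger directional evidence). Ties
  break to the lower gene index.
* **correlations** — |Pearson/Spearman/Kendall|; constant genes score 0
  (logged) so matrices stay finite.
* **wgcna** — soft-threshold adjacency |r|^softpower, used purely as an
  edge scorer (module detection is a different use case); optional
  topological-overlap variant behind a flag.
* **pcit** — for every trio, first-order partial correlations
  r_xy·z = (r_xy − r_xz·r_zy)/sqrt((1−r_xz²)(1−r_zy²)); the trio
  tolerance ε is the mean of the three |partial/direct| ratios, and (x,y)
  is flagged non-significant if for some z both |r_xy| ≤ ε|r_xz| and
  |r_xy| ≤ ε|r_yz|. Published variants of the significance rule differ in
  details; this rule is isolated in one function for substitution. Trios
  with |r| = 1 denominators or zero direct correlations are skipped
  (logged).
* **genie** — per target, a random-forest regression on the candidate
  regulators (itself excluded); edge scores are impurity-reduction
  importances normalized to sum 1 per nonconstant target. Defaults
  n_trees = 1000 and sqrt feature sampling; tests use fewer trees purely
  for speed, which leaves rankings intact at the tested sizes.

## Supervised inference

One binary classifier per TF: genes are instances, the TF's known targets
positives, all other genes negatives (the standard closed-world training
assumption — unlabeled true targets act as label noise and bias scores
down, a known property of this family). An RBF-SVM with balanced class
weights, C = 1 and median-pairwise-distance bandwidth is trained under
stratified 3-fold cross-validation over genes, so each gene's decision
value comes from folds that never saw its label, averaged over 3
independent split repetitions to reduce split variance. TFs with fewer
than `min_positives` (default 2) usable targets are skipped and listed.

Feature representation: by default each gene is embedded as its vector of
**absolute Pearson correlations** to every gene. A regulon under the
simulator mixes activated and repressed targets whose profiles are
anti-correlated; the magnitude embedding folds both onto the same side so
one classifier can learn regulon membership regardless of sign.
`features="profile"` uses the per-gene z-scored expression profile
directly (squared Euclidean distance then equals an affine function of
Pearson correlation). All hyperparameters are exposed; the defaults are
the package's own choices.

## Evaluation

The candidate universe is every ordered non-self gene pair (directed
mode; rows restricted to the scorer's declared regulators when present)
or every unordered pair (undirected mode, gold collapsed by logical OR,
directed scores by their maximum). Pairs absent from the gold standard
are negatives (closed world). Training pairs can be excluded and the rows
restricted so different methods are compared on an identical universe;
TF–TF pairs can optionally be excluded. The default mode is undirected
for symmetric scorers and directed for genie/sirene — each method is
evaluated on the claim it can actually make.

AUC is the tie-aware midrank rank-sum statistic, equal to the fraction of
positive–negative pairs correctly ordered with ties counted ½; it is
checked against a brute-force pair-counting oracle to 1e-12. ROC points
come from scikit-learn.

Sweeps enumerate a parameter grid in insertion order (ties in best-AUC
selection break to the first row); failing configurations are recorded
and the sweep continues. The canonical MI bin list is 2–10 by 1 then
15–95 by 5 (26 values), giving 312 MI-method configurations; the WGCNA
grid is 3 correlation kinds × softpower 7–17 (33). `sweep_mi_methods`
shares each MI matrix across rn/clr/aracne/mrnet since the matrix
dominates the cost. Group comparisons use two-sided Mann–Whitney U with
Bonferroni adjustment.

## Condition-network analysis

Pure set logic over positive-weight edges: the A-specific / B-specific /
shared partition with per-edge weight pairs; per-TF out-degrees;
regulator switches (targets whose sole regulator changes, grouped by the
ordered TF pair, with multi-regulator changes reported separately); and
edge overlap, operationalized as |E_A ∩ E_B| / |E_A| × 100 with the
reference network's edges optionally restricted to its top-k weights
(a Jaccard variant and undirected matching are available behind flags,
since the overlap convention is not standardized).

For switch detection after inference, `dominant_regulator_network`
reduces any score matrix to a single-regulator network (each non-TF gene
assigned its best-scoring TF). Knockdown data with Spearman correlation
scores is the cleanest route to this reduction, since clamping a TF
directly moves its targets.

## Problem sizes in the test suite

The bundled tests run the full pipeline at reduced scale, chosen to keep
the whole suite in the low minutes on one CPU while preserving the
qualitative effects: 100-gene networks with 5 seeds and a reduced MI grid
(2 estimators × 3 discretizations × bins {3, 5, 7}) for the data-type
comparison; 3 seeds for the supervised-vs-unsupervised comparison; 150-node
sources and 12 subnetwork datasets per density for the density effect;
50-gene networks for switch recovery.

## Known limitations

* The simulator's regulation function is a product of independent Hill
  terms; combinatorial logic and saturation interactions between
  regulators are not modeled.
* SynTReN- or GeneNetWeaver-specific behaviours are not reproduced
  bit-for-bit; only the experiment designs and their statistical structure
  are emulated.
* The `sg` estimator is the pseudocount plug-in, not the full posterior
  mean entropy.
* Kendall correlations are computed pairwise in Python and are the slow
  path for large gene sets.
* Supervised inference treats unlabeled pairs as negatives; scores for
  TFs with very small regulons are noisy, and decision values are not
  calibrated probabilities.
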