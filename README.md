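# grnbench

Benchmarking pipeline for gene-regulatory-network inference (GRNI).

Reconstructing the directed network of transcription-factor (TF) → target
regulation from expression data is a core problem in systems biology, and
dozens of inference methods exist with very different mathematical
foundations. `grnbench` is for computational biologists who want to compare
such methods under controlled conditions: it simulates benchmark networks
and steady-state expression data, runs eight unsupervised and one
supervised inference method under systematic parameter sweeps, scores every
prediction by AUROC against the known network, and compares
condition-specific networks to detect regulator switching.

## What is in the box

**Simulator** — directed TF→target networks (scale-free or Erdős–Rényi,
tunable density, acyclic by default) with Hill-kinetics regulation: gene
*i*'s steady level is

```
x_i = min(1, m_i · b_i · Π_a (ℓ + (1−ℓ)·A(x_a)) · Π_r (ℓ + (1−ℓ)·R(x_r)))
A(x) = x^n / (K^n + x^n),   R(x) = K^n / (K^n + x^n)
```

with basal activity *b*, basal multiplier *m*, leak ℓ, and per-edge Hill
parameters (n, K), solved by damped fixed-point iteration. Experiment
designs: wild type, per-gene knockdown (one sample per gene clamped to
0.01, plus wild type), and multifactorial (every sample perturbs all basal
activities by lognormal multipliers — a cohort of "patients"). Two-condition
models with planted regulator switches provide ground truth for
differential analysis.

**Inference methods** — mutual-information based (relevance networks,
CLR, ARACNE, MRNET) over a shared MI substrate with four entropy
estimators (`empirical`, `mm`, `shrink`, `sg`) and three discretizations
(equal frequency, equal width, global equal width); correlation-based
(Pearson/Spearman/Kendall, WGCNA soft-threshold adjacency |r|^β, PCIT
partial-correlation trio filtering); GENIE3-style per-target random-forest
importances; and SIRENE-style supervised inference (one cross-validated
SVM per TF trained on known targets).

**Evaluation** — tie-aware midrank AUROC over the closed-world candidate
edge universe (0.5 = random, 1 = perfect), directed or undirected;
parameter-sweep harness (the canonical MI grid spans 4 estimators × 3
discretizations × 26 bin sizes = 312 configurations); Mann–Whitney U
method comparison with Bonferroni correction.

**Network analysis** — edge differentials between condition networks,
regulator-switch detection, TF hub degrees, and edge-overlap validation.

## Worked example

```python
import grnbench as gb

net = gb.generate_source_network(50, tf_fraction=0.2, mean_degree=2.0, seed=1)
model = gb.assign_kinetics(net, seed=2)
data = gb.simulate_experiment(model, "multifactorial", n_samples=100, seed=3)
print(f"network: {len(net.nodes)} genes, {net.n_edges} edges, {len(net.tfs)} TFs")

sweeps = gb.sweep_mi_methods(data, net, methods=["rn", "clr"],
                             grid={"estimator": ["empirical", "mm"],
                                   "discretization": ["equalfreq", "equalwidth"],
                                   "bins": [3, 5, 7]})
for m, sw in sweeps.items():
    print(f"{m}: best AUC {sw.best.auc:.3f} at {sw.best.params}")

genie_auc = gb.roc_auc(gb.genie(data, n_trees=100, seed=4), net,
                       mode="directed").auc
print(f"genie: AUC {genie_auc:.3f} (directed)")
```

prints

```
network: 50 genes, 103 edges, 10 TFs
rn: best AUC 0.749 at {'estimator': 'mm', 'discretization': 'equalwidth', 'bins': 5}
clr: best AUC 0.739 at {'estimator': 'mm', 'discretization': 'equalwidth', 'bins': 5}
genie: AUC 0.752 (directed)
```

i.e. on a 50-gene multifactorial dataset all three methods recover the
network far above chance (AUC ≈ 0.74–0.75 versus 0.5), and the best MI
configuration here uses Miller–Madow entropies on 5 equal-width bins —
parameter choice matters, which is exactly what the sweep harness is for.

The same pipeline is available from the shell:

```
grnbench simulate --nodes 50 --design multifactorial --samples 100 --seed 1 --out-prefix bench
grnbench infer --expression bench.expr.tsv --method clr --out pred.tsv
grnbench evaluate --scores pred.tsv --gold bench.gold.tsv --expression bench.expr.tsv
```

## Documentation

See `docs/methods.md` for the model, estimator formulas, default
parameters and their rationale, numerical choices, and known limitations.
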