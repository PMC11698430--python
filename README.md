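# netbackbone

Statistical backbone extraction for weighted networks: seven
edge-significance filters, multiple-testing corrections, and a
benchmarking pipeline that compares what each filter keeps and throws
away.

## The problem

Weighted networks — connectomes, gene-interaction maps, food webs,
transport and social networks — are often too dense to analyse or
visualize directly. *Backbone extraction* reduces a network to its
essential edges. Naive weight thresholding destroys the natural
heterogeneity of edge weights, so statistical filters instead test each
edge against a null model of weight formation and keep the edges whose
observed weight is significantly larger than the null predicts: p-values
are computed per edge, optionally corrected for multiple testing, and
edges with p ≤ α are retained.

This package implements seven such filters behind one interface:

| name | null model | weights |
|---|---|---|
| `df` | disparity filter: node strength s_i split uniformly over its k_i edges; one-sided p = (1 − w/s_i)^(k_i−1) | any > 0 |
| `pf` | Pólya urn with reinforcement a: W ~ BetaBinomial(s_i, 1/a, (k_i−1)/a) | integer |
| `mlf` | marginal likelihood: W ~ Binomial(T, s_i s_j / 2T²) | integer |
| `nc` | noise-corrected (binomial approximation): W ~ Binomial(2T, s_i s_j / 4T²) | integer |
| `ecm` | enhanced configuration model: maximum-entropy ensemble constraining every node's degree *and* strength via multipliers (x_i, y_i); p = x_i x_j (y_i y_j)^w / (1 − y_i y_j + x_i x_j y_i y_j) | integer |
| `gloss` | global significance: weights reshuffled over the fixed topology; survival under the empirical weight law, by default conditioned on the endpoints' strengths and degrees | integer (conditional) |
| `lans` | locally adaptive sparsification: per-node empirical CDF, p = fraction of the node's incident edges strictly heavier | any > 0 |

For the one-sided filters (`df`, `pf`, `lans`) the edge p-value is the
minimum over the two endpoint views. Corrections: Bonferroni
(p·m capped at 1) and Benjamini–Hochberg step-up adjusted p-values.

On top of the filters sits the comparative pipeline used to benchmark
them: pairwise Spearman correlation of p-value vectors, asymmetric
backbone overlap |X∩Y|/|X|, correlation of p-values with edge weight /
edge degree k_i·k_j / edge betweenness, seven normalized global backbone
properties (edge, node and weight fractions, weight entropy,
reachability, component count, transitivity), KS-distance ranking of
backbone weight and degree distributions, and extraction-rate
accounting. Synthetic generators (heavy-tailed configuration-model
graphs with integer weights, optionally with planted anomalously strong
edges) make every stage runnable and testable without external data.

## Worked example

Plant a ground truth and see how two filters differ:

```python
from netbackbone import mlf_pvalues, disparity_pvalues, extract_backbone
from netbackbone.synth import gen_planted, recovery_metrics

planted = gen_planted(n=300, rho=0.05, boost=10, seed=1)
net = planted.net  # 5% of edges have their weight multiplied by 10
print(f"network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges, "
      f"total weight {net.total_weight:.0f}")
for name, pv in (("mlf", mlf_pvalues(net)), ("df", disparity_pvalues(net))):
    bb = extract_backbone(net, pv, alpha=0.05, correction="fdr_bh")
    pr = recovery_metrics(planted, bb)
    print(f"{name}: retained {bb.number_of_edges()}/{net.number_of_edges()} edges, "
          f"{bb.number_of_nodes()} nodes; planted-edge precision {pr.precision:.2f}, "
          f"recall {pr.recall:.2f}")
```

prints (exactly, seed 1):

```
network: 300 nodes, 837 edges, total weight 5187
mlf: retained 612/837 edges, 300 nodes; planted-edge precision 0.07, recall 1.00
df: retained 8/837 edges, 16 nodes; planted-edge precision 0.88, recall 0.17
```

The two filters sit
at opposite ends of the spectrum the benchmark quantifies: the
marginal-likelihood null is permissive — it catches every planted edge
but keeps most of the network — while the disparity filter is
aggressive, returning a tiny high-precision core at the cost of recall
and of isolating most nodes.

The same things are available from the shell:

```
backbone synthesize --model planted --n 300 --seed 1 --out net.tsv --labels labels.csv
backbone pvalues --input net.tsv --method mlf --out pv.csv
backbone extract --input net.tsv --pvals pv.csv --alpha 0.05 --correction fdr_bh --out backbone.tsv
backbone run --config examples/run.yaml
```

`backbone run` executes the full comparative pipeline from a YAML config
(see `examples/run.yaml` for the schema: network paths or synthetic
specs, methods and their parameters, α, corrections, experiment list,
output directory, seed) and writes tidy CSV tables — similarity and
overlap μ/σ matrices, per-property correlation records, normalized
global properties with their pooled counter-cumulative distributions,
KS ranks, extraction rates — plus a JSON manifest recording the config,
every network, and any per-(network, method) failure.

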