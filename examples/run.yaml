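# Full comparative run on a synthetic corpus.
# `networks:` may list edge-list TSV / GraphML paths instead of (or in
# addition to) synthetic specs; per-network seeds derive from `seed`.
synthetic:
  - model: heterogeneous   # heterogeneous | planted | fixture
    count: 10
    n: 300
    mean_degree: 6.0
    degree_exponent: 2.5
    weight_model: lognormal_int   # lognormal_int | zipf_int | poisson_shifted
methods: [df, pf, mlf, nc, ecm, gloss, lans]
method_params:
  pf: {a: 1.0}
  gloss: {mode: conditional}
alpha: 0.05
corrections: [none, fdr_bh]
experiments: [similarity, overlap, local, global, distributions, extraction]
min_edges: 1000      # eligibility for the distribution-rank study
out_dir: results/run
seed: 0
log_level: INFO
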