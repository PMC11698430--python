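# Methods

This note documents the models behind each filter, the solver and
numerical choices, what the synthetic generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Notation

An undirected simple network with positive edge weights w_ij. Node
degree k_i (incident edge count), strength s_i = Σ_j w_ij, total weight
T = Σ_{i<j} w_ij, total strength N_t = Σ_i s_i = 2T. A filter assigns
each edge a p-value under a null model of weight formation; a backbone
at level α retains edges with (optionally corrected) p ≤ α, keeping
boundary ties. Nodes that lose every incident edge leave the backbone —
otherwise the node fraction would be identically 1 and node-preservation
contrasts between filters would be invisible.

## The seven nulls

**Disparity (df).** A node of degree k splits its strength uniformly at
random over its k edges; a normalized weight x = w/s then behaves like
the smallest spacing of k−1 uniform points, with survival
(1−x)^(k−1). Endpoints with k = 1 carry a degenerate null (their single
edge is their whole strength) and contribute the non-informative p = 1.
Edge p = min of the two endpoint values.

**Pólya urn (pf).** The node allocates its s integer weight units one at
a time; a unit lands on an edge with probability proportional to
(current weight)·a + 1. The marginal weight of one edge is
BetaBinomial(n = s, α = 1/a, β = (k−1)/a); one-sided p is the survival,
computed from log-gamma/log-beta with a reverse-cumulated pmf per node
(one table serves all the node's edges). The reinforcement a is the only
free parameter: a → 0 recovers Binomial(s, 1/k); a = 1 makes the weight
fractions uniform on the simplex, the finite-s analogue of the
disparity null; a → ∞ polarizes allocations so that any observed split
is typical and the survival tends to 1/k, independent of the weight.
The library default is a = 1. The comparative studies in
`scripts/acceptance.py` run pf in the strong-reinforcement regime
(a = 1000) because that regime — and on internally homogeneous weights
only that regime — produces the filter's characteristic decoupling of
significance from raw edge weight; see "Open choices" below.

**Marginal likelihood (mlf).** Each of T total weight units is an
independent trial that lands on the pair (i, j) with probability
q_ij = s_i s_j / (2T²); the edge weight is Binomial(T, q_ij) and the
symmetric p-value its survival P(X ≥ w), evaluated through the
regularized incomplete beta (scipy's binomial survival), never by
explicit summation. q is clipped to 1 with a warning in the (extreme)
case s_i s_j > 2T².

**Noise-corrected, binomial approximation (nc).** Identical construction
with n = N_t trials and q_ij = s_i s_j / N_t². MLF and NC share the null
mean s_i s_j / N_t and both conserve expected total weight; they differ
only in the trial convention and hence in variance, which is why their
p-value vectors correlate near 1 yet are not identical. The original
noise-corrected filter's full Bayesian posterior-variance mode (Δ
threshold) is out of scope; only the stated binomial approximation is
implemented.

**Enhanced configuration model (ecm).** The maximum-entropy ensemble of
weighted networks whose expected degree *and* strength sequences match
the observed ones. Per node pair, with u = x_i x_j, z = y_i y_j and
D = 1 − z + u z: connection probability p_ij = u z / D, weight law
q(w) = u z^w (1−z)/D for w ≥ 1, survival P(W ≥ w) = u z^w / D (a
geometric tail). The p-value is that survival at the observed weight.

*Fitting.* The ensemble is an exponential family in (ln x, ln y) whose
sufficient statistics are exactly the degree and strength sequences, so
the multipliers maximize a concave log-likelihood and the likelihood
gradient *is* the vector of constraint residuals k_i − ⟨k_i⟩,
s_i − ⟨s_i⟩. The solver runs L-BFGS-B from the deterministic point
x_i = k_i/√(Σk), y_i = s_i/(1+Σs) (bound y < 1), then polishes with a
damped Newton iteration whose Jacobian is the analytic Hessian — the
covariance matrix of the sufficient statistics, with closed-form
Bernoulli/geometric pair moments. Tolerance 1e-6 on both residual
maxima, max 5000 iterations, no randomness. A plain fixed-point
iteration on the multiplier update maps was tried first and discarded:
it settles into two-cycles on heterogeneous networks.

*Infeasibility.* Two real failure modes are detected and reported as
errors naming the offending nodes rather than returned as bad fits:
(i) a node adjacent to all others — its degree constraint Σ_j p_ij = n−1
cannot be met because every p_ij < 1 strictly; (ii) a low-degree node
whose strength far exceeds what its partners' weight scales support —
its y multiplier is pushed to the y = 1 boundary with a non-vanishing
residual. Both occur in practice (the unit triangle; small heavy-tailed
networks), which is the mechanistic reason the ecm column of the
extraction-rate table sits well below 100%.

**Global significance (gloss).** Null: the topology is frozen and every
edge weight is redrawn from the empirical weight distribution P̂ of the
whole network. Two readings are provided. *marginal*: one draw from P̂
per edge, p = Pr(W ≥ w) — simple, but then p is a monotone function of
the weight alone (rank correlation with weight exactly −1). *conditional*
(default): the null law of the edge's weight given the endpoints'
observed strengths and degrees, treating each endpoint's other k−1
incident weights as i.i.d. draws from P̂:

    p(w | s_i, s_j, k_i, k_j) ∝ P̂(w) · Q^(k_i−1)(s_i − w) · Q^(k_j−1)(s_j − w)

with Q^(m) the m-fold convolution of P̂ on the integer grid
(Q^(0) = point mass at 0), convolution powers cached per degree. The
p-value is the normalized upper tail from the observed weight. A
degree-1 endpoint pins the edge weight to its strength, giving p = 1;
an empty conditional support also returns p = 1 with a warning.

**Locally adaptive sparsification (lans).** One-sided p from endpoint i
is the fraction of i's incident edges *strictly* heavier than the edge;
edge p = min over endpoints. Strict counting gives every node's
heaviest edge p = 0, so no node can lose all its edges at any positive
α — the node-preserving behavior that distinguishes this filter. The
inclusive (≥) counting variant would instead give the top edge p = 1/k
and destroy that property; it is exercised in the tests as a contrast
but not offered as an option.

## Corrections and extraction

Bonferroni (p·m capped at 1) and Benjamini–Hochberg step-up adjusted
p-values, both delegated to statsmodels and cross-checked in the tests
against a brute-force step-up rejection oracle. m is the network's edge
count: every edge is tested once, per network and per method.
Corrections return adjusted p-values rather than reject flags so the
similarity study can correlate corrected vectors directly. Retention
uses p ≤ α.

## Evaluation measures

Spearman correlation is tie-aware (mean ranks; scipy), returned as
missing with a warning on constant input. Overlap is the asymmetric
per-viewpoint coefficient |X∩Y|/|X|, which makes the overlap matrix
asymmetric and containment readable off a row. Edge degree is k_i·k_j.
Edge betweenness sums over unordered node pairs the fraction of
shortest paths through the edge, on the unweighted topology by default —
hop counts are the literal reading of the formula and avoid choosing a
weight-to-distance transform; `weighted=True` (distance 1/w) is
available. Weight entropy is Shannon entropy in bits of the weight
shares q_e = w_e/Σw — scale-invariant and defined for any positive
weights; a binned-histogram alternative is exposed as a parameter.
Reachability is the fraction of ordered node pairs joined by a path,
over the graph's own node set. Transitivity is 3·triangles/triples.
The KS statistic is the maximum ECDF gap (scipy), with a brute-force
double-loop scan as the test oracle. Normalized global properties are
ratios to the original network's value; ratios with zero or undefined
denominators are reported missing, as are all downstream cells of an
empty backbone (mirroring the < 100% extraction rates rather than
zero-filling them).

## Synthetic generator

`gen_heterogeneous` draws a truncated power-law degree sequence
(default exponent 2.5, cutoff √(n·mean_degree), continuous
inverse-CDF sampling rounded to integers with the Pareto scale solved
numerically so the rounded, truncated law hits the requested mean
degree), wires it with the configuration model collapsed to a simple
graph, keeps the largest connected component (so reachability and
component count of the original are exactly 1 and the normalized ratios
are well-defined), and assigns i.i.d. integer weights ≥ 1: rounded
log-normal(μ=1, σ=1) by default, or Zipf(2.5) ranks, or 1+Poisson(3).
Defaults (n = 500, mean degree 6) give networks in the density range
typical of the empirical corpora these filters are applied to. Every
generator is a pure function of its parameters and seed.

`gen_planted` multiplies a seeded random fraction ρ of edge weights by
an integer boost factor B (multiplicative, so the planted signal is
scale-free across weight models) and returns the labels, enabling
precision/recall evaluation that real data cannot provide.

What the generator does *not* emulate: weight–topology coupling. Real
weighted networks often carry systematically heavier weights on
hub–hub edges (gravity-like transport flows, connectome projections);
here weights are i.i.d., independent of the degrees. Consequences:
passing directional tests shows the filters' *mechanisms* behave as
described (local weight ranking for df/lans, degree-and-strength
discounting for ecm, weight-typicality for pf at strong reinforcement),
not that effect sizes on any real corpus are reproduced. Community
structure, clustering above the configuration-model baseline, and
degree assortativity are likewise absent.

## Open choices, resolved

- **Pólya reinforcement.** With i.i.d. weights, pf at a = 1 ranks edges
  almost exactly like df (median Spearman(p, w) ≈ −0.94 on the study
  corpus), for any moderate a. The characteristic pf behavior — edge
  significance unrelated to raw weight, with small spread — emerges only
  in the strong-reinforcement regime (measured: median ≈ −0.07 at
  a = 1000). The studies therefore run pf at a = 1000 while the
  single-edge default stays a = 1; both are plain parameters of
  `polya_pvalues`.
- **GloSS mode.** Conditional is the default; the marginal reading is
  kept because it is the literal "draw from the empirical distribution"
  null, but its perfect anticorrelation with weight makes it
  uninformative as a *filter* comparison axis.
- **Similarity alignment.** P-value vectors are correlated over each
  network's full edge set (every method scores every edge), so no
  imputation or subsetting is needed.
- **Aggregation.** μ/σ matrices use the population standard deviation
  (divisor N).
- **Determinism.** Node identifiers are opaque strings; all iteration
  that reaches an output file is lexicographically ordered; the
  pipeline's one global seed fans out to per-stage seeds by stable
  CRC32 hashing of (seed, stage, indices), so adding a network never
  perturbs another cell's randomness. Repeated runs are byte-identical.

## Numerical notes

Binomial and beta-binomial survivals are computed via regularized
incomplete beta / log-gamma, never by naive pmf summation in linear
space (the pf per-node table sums in linear space only after a log-space
pmf, and re-clips to [0, 1]). The ecm survival uses the closed-form
geometric tail, not series summation. GloSS convolution powers grow as
m·w_max and are computed once per distinct degree. Problem sizes in the
shipped studies (20 networks, n = 300) were chosen so the full suite and
the acceptance script each run in minutes on a single core; all scale
parameters are plain arguments.

## Known limitations

- ecm fitting is dense O(n²) per iteration; practical to a few thousand
  nodes, not beyond.
- pf requires integer weights and per-node tables of length s_i + 1;
  strengths in the millions would need an asymptotic tail instead.
- The gloss conditional null treats the two endpoints' residual
  strengths as independent given the edge weight — the same
  approximation the convolution formulation always makes; the
  weight-shuffle tests bound its error only on small fixtures.
- No directed, bipartite, or multigraph variants; structural filters
  (MST, k-core, thresholding) are deliberately out of scope.
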