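# Methods

## Model and procedure

The package scores a pathway's activity per sample and ranks its nodes by
leave-one-out perturbation of the case/control contrast in that score. The
ingredients, in the order they are computed:

**Marginal statistics.** Each node gets a Welch (unequal-variance,
two-sided) two-sample t statistic and p-value for the grp1−grp2 contrast,
plus its observed expression maximum O_j. Welch is used rather than the
pooled-variance test because the pathway-level statistic t_all combines
per-group standard errors the same way; the two conventions should agree.
A node with zero variance in both groups is assigned t = 0, p = 1 with a
warning, which removes it from every gated weight.

**Local weight L.** −log p_j for nodes with p_j < α_L, normalized to sum
one. The logarithm base is immaterial to L (it rescales numerator and
denominator identically); natural log is used internally, which also makes
the α_L = 1 numerator sum equal to half of Fisher's combined statistic
−2Σ ln p. A numerically zero p-value is clamped to the smallest positive
float so a single underflowing node cannot absorb all weight.

**Topology weight S.** For node j, Σ_{k≠j} |ρ_jk|/d_jk over pairs with
path length strictly below D, gated on the node's own p_j < α_S, then
normalized. Correlations are Pearson, computed once on the pooled sample
(cases and controls together) from the raw, un-regularized expression:
regularization only reflects columns, which the absolute value erases, and
pooling is the natural choice when the correlation is meant to describe
the biology rather than either phenotype stratum (group-wise correlation
is a plausible alternative; it is not implemented). Disconnected pairs
(d = ∞) contribute nothing, so isolated nodes always have S_j = 0 while
keeping their L_j. Both indicators are strict inequalities.

**Direction regularization.** Columns with t_j < 0 are reflected:
g^R = O_j − g + ε (default ε = 0.001). This re-orients every node so that
"more active" points the same way before summation; the reflected column's
recomputed t is nonnegative. A useful identity: swapping which group is
grp1 flips every t_j, reflects the complementary column set, and maps g^R
to (O_j + ε) − g^R, which leaves the pipeline-level t_all (and hence every
influence value Q_j) exactly invariant.

**Score and statistic.** T_i = Σ_j g^R_ij (L_j + S_j);
t_all = (T̄_grp1 − T̄_grp2)/√(se₁² + se₂²). If one weight vector is
all-zero (its gate admitted nothing) the other alone carries the score; if
both are all-zero the score falls back to uniform weights 1/M with a
prominent warning. Degenerate zero-variance scores return t_all = 0.

**Leave-one-out ranking.** For each node, the (M−1)-node subnetwork is
formed and path lengths, both weight normalizations, and the score are
rebuilt; Q_j = |t_all − t_(−j)|. Marginal statistics and pairwise
correlations are reused across deletions because deleting a third node
cannot change them — only distances, indicator sets and the two
normalizing denominators respond to the deletion, and those are always
recomputed. Ties in Q (and in the comparator's p-values) break toward the
larger degree, then input order, so output is deterministic. The
influential-node cutoff is the first interior position j (2 ≤ j ≤ len−1)
of the descending Q sequence whose second difference
(Q_(j+1) − Q_(j)) − (Q_(j) − Q_(j−1)) is negative; nodes ranked strictly
before it are influential. There may be no such position, in which case no
cutoff is reported.

**Permutation test.** As supporting plumbing, a label-permutation p-value
for |t_all| is provided: (1 + #{|t^(b)| ≥ |t|})/(B + 1) over B simple
label permutations, recomputing node tests, gates, regularization and the
score per permutation (correlations and distances involve no labels and
are reused). The null is plain exchangeability of samples; no
stratification is attempted.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α_L | 0.05 | p-value gate for the local weight; 1 opens it fully |
| α_S | 1.0 | p-value gatekeeper for the topology weight |
| D | ∞ | strict upper bound on path lengths entering S (edge steps) |
| ε | 0.001 | reflection offset keeping regularized maxima positive |
| hub threshold | 3 | degree at or above which a node is annotated a hub |
| decision point x | 3 | top-x window used by the evaluation metrics |

## Synthetic study design

`make_prototype_network` builds a deterministic 32-node pathway with two
designated hubs of degrees 17 and 8 — the shape of a mid-sized signaling
pathway whose central transcription-factor node dominates the degree
distribution — with every other node of degree ≤ 2 and the graph
connected. Expression is zero-mean multivariate normal with target
correlation ρ₀^d_jk (default ρ₀ = 0.4; the matrix is eigenvalue-clipped to
the nearest unit-diagonal PSD matrix if needed), so directly interacting
nodes are the most correlated — precisely the structure the topology
weight exploits. Disease status follows
logit(p_i) = β₀ + Σ_j β_j G_ij with β₀ = 0 on column-standardized
expression; subjects are drawn from a pool of 400 (grown geometrically if
exhausted) until exactly 50 cases and 50 controls are retained. Scenarios
A–D set (causal hubs, β_hub, causal non-hubs, β_nonhub) to (2, 1.0, 8,
0.1), (2, 0.5, 8, 0.1), (2, 0.1, 8, 0.1) and (0, 0, 0, 0); the causal
non-hubs are drawn uniformly among degree-≤2 nodes once per study. Studies
default to 1000 replications; replication r derives its random stream from
the pair (base seed, r), so studies are reproducible and replications
independent.

**Metrics.** HRR at decision point x is the fraction of replications in
which at least one designated hub ranks in the top x. This indicator
reading is used (rather than averaging the count of hubs in the top x
divided by x) because its chance level under a uniformly random ranking
has the closed form 1 − C(M−H, x)/C(M, x) = 18.1% at (32, 2, 3), the
calibration constant the evaluation is anchored to; the count-based
variant is available behind `literal_count=True`. FDR and TDR among the
top x are per-replication counts (with FDR ≡ 1 and TDR undefined in the
null scenario) averaged over replications.

**What the generator does and does not emulate.** It reproduces the
correlation-decays-with-distance structure and the logistic case/control
mechanism, but not the heterogeneous variances, skewness, outliers and
partially topology-free correlation of real tumor expression. Two
consequences matter when reading test results. First, under the null
scenario the marginal-effect ranker's hub ranking rate lands somewhat
below the closed-form chance level (≈13–16% rather than 18.15%): the hubs
sit inside the large positively correlated block, extremes among
correlated variables are rarer than among exchangeable ones, and the two
hubs' top-x events are themselves positively dependent. Second, causal effects injected directly on clean Gaussian
nodes give the marginal t-test an unrealistically crisp signal: under the
strong-effect scenario both the t-test ranker and the network-based
ranking saturate near HRR = 1, so comparisons between methods at that
ceiling are decided by sub-percent noise and say little about real data,
where marginal signal is far noisier and network information earns its
keep. The network ranking's distinctive behavior is clearest under the
null scenario, where it still places hubs ahead of chance purely on
topology.

## Numerical choices

- Shortest paths by BFS (scipy.sparse.csgraph) on the dense adjacency;
  distances are exact small integers, ∞ for disconnected pairs.
- Weight normalizations are plain sums; vectors sum to 1 within 1e−12
  whenever non-degenerate.
- The leave-one-out loop reuses one regularized expression matrix and one
  correlation matrix; per deletion it runs one BFS and a handful of O(M²)
  array operations, so a 32-node, 100-sample replication costs ~15 ms.
- Influence values are compared exactly for ordering; the only tolerance
  in the pipeline is the 1e−12 normalization check in tests.
- An inert isolated node (no edges, constant expression) has Q = 0 up to
  float roundoff (~1e−16), not exactly, because its removal perturbs
  summation order.

## Known limitations

- Edges are undirected and unweighted; KEGG relation direction and subtype
  are discarded, as only minimum step counts enter the method.
- The KGML reader is a documented best-effort parser (gene/compound/
  ortholog and group entries, relations as undirected edges), not a
  bit-compatible port of any other tool's collapsing rules.
- Multi-gene nodes are aggregated by the arithmetic mean of member genes
  (median behind a flag); no expression-level normalization or QC is
  performed — inputs are assumed already processed.
- Only the t-statistic reference is implemented for direction
  regularization; mean-difference or fold-change references are not.
- Group-wise (per-phenotype) correlation for S is not implemented.
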