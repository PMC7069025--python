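# networkhub

Prioritization of hub gene nodes in biological pathway networks.

Most gene-ranking procedures order the members of a pathway by marginal
effect alone — a t statistic or fold change per gene — and implicitly assume
the genes are independent and exchangeable. Hub nodes violate both
assumptions: they sit at common connection points, interact with many
neighbors, and can matter to the pathway even when their own differential
expression is unremarkable. `networkhub` implements a procedure that folds
the network itself into the ranking: it builds a per-sample **pathway
activity score** from both marginal and topological evidence, then ranks
each node by how much the case/control contrast in that score moves when
the node is deleted from the network.

It is aimed at analysts with a case/control expression study (RNA-Seq or
microarray), a pathway of interest (KEGG or user-defined edge list), and
the question *which nodes in this pathway should be followed up first?*

## The method

For samples *i* = 1..*N* and pathway nodes *j* = 1..*M*:

1. **Local weight** — per-node Welch t-test p-values *p_j* between the two
   phenotype groups give

   *L_j* = −log *p_j* · I(*p_j* < α_L) / Σ_m [−log *p_m* · I(*p_m* < α_L)],

   so marginally significant nodes are up-weighted on an exponential scale
   (default α_L = 0.05; with α_L = 1 the numerators sum to half of Fisher's
   combined statistic).

2. **Topology weight** — with |ρ_jk| the absolute Pearson correlation and
   *d_jk* the shortest path length (edge steps) between nodes,

   *S_j* = Σ_{k≠j} (|ρ_jk| / d_jk) · I(d_jk < D, p_j < α_S), normalized to sum 1.

   Correlation between distant nodes is damped by path length — two highly
   correlated but far-apart genes are unlikely to interact directly.
   Defaults: D = ∞ (all connected pairs), α_S = 1 (every node contributes).

3. **Direction regularization** — columns with negative t are reflected
   about their observed maximum, g^R_ij = O_j − g_ij + ε, so negatively
   associated nodes add to the score instead of cancelling.

4. **Activity score and statistic** — T_i = Σ_j g^R_ij (L_j + S_j);
   t_all = (T̄_grp1 − T̄_grp2) / √(se₁² + se₂²).

5. **Leave-one-out ranking** — deleting node *j* and rebuilding path
   lengths, both weight normalizations and the score gives t_(−j); the
   influence Q_j = |t_all − t_(−j)| ranks the nodes, and the first downward
   bend of the sorted-Q scree curve (negative second difference) cuts off
   the "influential" set.

A simulation module reproduces the method's evaluation design on a
synthetic 32-node pathway with two designated hubs (degrees 17 and 8):
expression with correlation decaying as ρ₀^d, disease status from
logit(p_i) = β₀ + Σ β_j G_ij across four effect-size scenarios, and
rankings scored by hub ranking rate (HRR), false discovery rate and true
detection rate at a decision point *x*.

## Worked example

Rank the nodes of one simulated strong-effect dataset (scenario A: both
hubs causal with β = 1, eight non-hubs with β = 0.1, 50 cases / 50
controls):

```python
import numpy as np
import networkhub as nh
from networkhub.simulation import simulate_expression, assign_disease

net, hubs = nh.make_prototype_network()
scenario = nh.SimulationScenario.from_id("A").resolve(
    net, hubs, np.random.default_rng([7, 0]))
rng = np.random.default_rng([7, 1])
pool = simulate_expression(net, n_pool=400, seed=rng)
labels, expr = assign_disease(pool, scenario, seed=rng)

res = nh.loo_rank(expr, labels, net)
print(f"t_all = {res.t_all:.4f}")
for n in res.order[:5]:
    print(n, res.degree[n], f"p={res.p_value[n]:.2e}",
          f"L={res.L[n]:.3f}", f"S={res.S[n]:.3f}", f"Q={res.Q[n]:.4f}")
print("influential:", res.influential)
```

prints

```
t_all = 7.3939
H02 8 p=1.40e-05 L=0.118 S=0.069 Q=0.4716
N03 2 p=3.35e-03 L=0.060 S=0.025 Q=0.2533
N25 1 p=5.90e-04 L=0.079 S=0.021 Q=0.1966
H01 17 p=3.60e-07 L=0.157 S=0.121 Q=0.1906
N18 1 p=1.92e-02 L=0.042 S=0.017 Q=0.1703
influential: ('H02', 'N03', 'N25')
```

The strongest influence (Q = 0.47) belongs to the degree-8 causal hub H02,
which also carries the second-largest local and topology weights; the
scree-curve inflection at position 4 declares the top three nodes
influential. The same pipeline runs on real data from the command line:

```bash
networkhub rank --expr expr.tsv --labels labels.tsv --network edges.tsv --out results/
networkhub simulate --scenario A --reps 1000 --seed 1 --out sim/
networkhub chance-hrr --nodes 32 --hubs 2 --x 3   # -> 0.1815
```

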