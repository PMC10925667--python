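# netspread

Reaction–diffusion propagation models on structural connectomes.

Network diffusion is a popular model for the progression of degenerative
brain diseases and traumatic brain injuries, but it conserves the total
amount of the spreading quantity — a poor assumption for damage or
misfolded-protein load, which grows or recedes. `netspread` implements the
natural extension: graph Laplacian diffusion coupled to a local reaction
term, turning conservative spreading into propagating invasion fronts
whose fate depends on the reaction kind, the seed location and the seed
size. It is intended for computational neuroscientists and applied
mathematicians exploring propagation phenomenology on connectome graphs.

## Model

A connectome is an undirected graph over `N` regions of interest (ROIs)
with adjacency matrix `A`, obtained from a weighted structural matrix `W`
by thresholding: `A_ij = 1` iff `W_ij ≥ S_w`. With degrees
`k_i = Σ_j A_ij` and Laplacian `L = A − K` (`K = diag(k)`), the
concentration `θ_i(t)` of damage/substance in node `i` follows

    dθ_i/dt = w Σ_j (A_ij θ_j − k_i δ_ij θ_j) + r g(θ_i)

i.e. `θ' = w L θ + r g(θ)`. Available reaction terms `g`:

| kind | g(θ) | behaviour |
|---|---|---|
| `none` | 0 | pure diffusion, `θ(t) = exp(wLt) θ(0)`, conserves mass |
| `logistic` | θ(1−θ) | FKPP growth; any positive seed invades |
| `strong_allee` | θ(θ−θ_c)(1−θ) | negative per-capita growth below θ_c: sub-threshold states die out |
| `neutral_allee` | max((θ−θ_c)(1−θ), 0) | zero growth below θ_c: sub-threshold states freeze |

Summary observables: the mean concentration `M(t) = (1/N) Σ_i θ_i(t)` and
the count `N(t; θ_c)` of nodes strictly above the threshold θ_c. The
*invasion value* of a seed node is the minimal initial concentration `θ_0`
injected there for which the dynamics asymptotically fill the graph
(`M → 1`, `N → N`); it is estimated by bisection.

Because the reference connectome derives from a restricted-access imaging
dataset, the package ships a synthetic-connectome generator that
reproduces its published graph statistics (379 nodes, 1,738 links at
`S_w = 0.034`, hub degree 36, a pendant node, full connectivity) so the
whole pipeline is reproducible end to end.

## Worked example

```python
from netspread import (GeneratorSpec, ReactionSpec, SimulationConfig,
                       generate, invasion_value, summarize, threshold_adjacency)

W = generate(GeneratorSpec(rng_seed=42))          # synthetic 379-node connectome
G = threshold_adjacency(W, 0.034)
s = summarize(G)
hub, pendant = s.max_degree_node[0], s.min_degree_node[0]

spec = ReactionSpec(kind="neutral_allee", r=1.0, theta_c=0.001)
cfg = SimulationConfig(w=1.0, reaction=spec, t_max=80.0, dt=4.0)
for name, node in (("hub", hub), ("pendant", pendant)):
    est = invasion_value(G, spec, cfg, node, bracket=(1e-4, 1.0), tol=1e-3)
    print(name, G.degrees[node], round(est.value, 4))
```

prints

```
hub 36 0.315
pendant 1 0.0113
```

Seeding the best-connected node requires a ~28× larger initial
concentration to invade than seeding the pendant: the hub's 36 links
dilute the seed below the Allee threshold before the reaction can amplify
it, while the pendant's single link retains concentration long enough to
ignite a self-sustaining front. The `examples/` directory walks through
the other capabilities (generator, diffusion vs reaction, Allee regimes),
each printing the numbers it computes.

A thin CLI wraps the same API:

```
netspread gen-connectome --n 379 --links 1738 --hub-degree 36 --rng-seed 42 --out net
netspread stats --weights net.csv --threshold 0.034
netspread simulate --weights net.csv --seed-node 379 --theta0 0.1 \
    --reaction neutral-allee --t-max 80 --dt 4 --out run
netspread invasion-scan --weights net.csv --seed-node 1 --seed-node 379 \
    --reaction neutral-allee --out scan.csv
```

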