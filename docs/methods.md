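# Methods

## Model

The package integrates the node-wise ODE system

    dθ_i/dt = w (Σ_j A_ij θ_j − k_i θ_i) + r g(θ_i),    θ_i ∈ [0, 1]

on an undirected, unweighted graph: conservative Laplacian diffusion
(`L = A − K`, zero row sums, negative semidefinite) plus a spatially
homogeneous local reaction. Assumptions baked into the implementation:

- the graph is simple (no self-loops, no multi-edges) and, for most
  analyses, connected — pure diffusion then relaxes to the uniform state
  `θ_0/N` along the Laplacian spectrum, the slowest mode decaying at rate
  `w·λ₂` (algebraic connectivity);
- the reaction is local and identical in every node (one scalar rate `r`,
  one threshold `θ_c`); carrying capacity is normalized to 1;
- the dynamics are deterministic; time units are arbitrary, so all times
  reported are in units of `1/r` when `r = 1`.

Reaction terms: logistic `θ(1−θ)`, strong Allee `θ(θ−θ_c)(1−θ)` and
neutral Allee `max((θ−θ_c)(1−θ), 0)`. All three share the homogeneous
fixed points θ = 0 and θ = 1. The neutral term dominates the strong term
pointwise on [0, 1] (the strong term is the neutral one scaled down by
θ ≤ 1, minus its negative sub-threshold branch), which is why
strong-Allee invasions are systematically slower. The reaction registry
is extensible with any `(θ, θ_c) → rate` callable.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `w` | diffusion rate (1/time) | 1 | reference parameterization |
| `r` | reaction rate (1/time) | 1 | reference parameterization |
| `θ_c` | Allee threshold (concentration) | 0.001 | reference value; also used as the counting threshold in `N(t; θ_c)` so "above threshold" means "reaction active" |
| `S_w` | edge threshold on `W` | 0.034 | largest value keeping the reference graph fully connected |
| `θ_0` | seed concentration | run-specific | the experimental variable |

The threshold in `N(t; θ_c)` uses the Heaviside convention Θ(0) = 0: a
node exactly at θ_c is *not* counted, and thresholding `W` is inclusive
(`W_ij ≥ S_w` connects).

## Numerical integration

- **rk45** (default): adaptive embedded Runge–Kutta via
  `scipy.integrate.solve_ivp`, `rtol = 1e-8`, `atol = 1e-10`. The
  absolute tolerance sits two orders below `θ_c = 1e-3` because
  invasion/extinction classification hinges on resolving concentrations
  near the threshold.
- **euler**: fixed-step explicit forward Euler, the simplest scheme for
  these dynamics and the independent oracle the adaptive path is tested
  against. A stability guard caps the step at
  `0.5 / (w·k_max + r·sup|g′|)` with `sup|g′| ≤ 1 + θ_c` on [0, 1] for
  the cubic family; a larger requested step is reduced with a warning.
- **expm**: the closed-form `θ(t) = exp(wLt) θ(0)` for pure diffusion,
  evaluated as a matrix-exponential action (`expm_multiply`), never by
  forming the dense exponential. Valid only for reaction kind `none`.

Stopping rule: every run ends at the first output sample (for rk45, a
terminal event) where `max_i |dθ_i/dt| < 1e-10`, or at `t_max`. The rule
is recorded in the trajectory provenance. In practice the event rarely
fires on large invaded runs — solver noise at the `atol` scale keeps the
numerical derivative slightly above 1e-10 — so endpoint classification is
designed to read the final sampled state and carries a `converged` flag
instead of pretending asymptotic certainty.

Negative clipping (`clip_negative`, default on) zeroes transient negative
concentrations in stored states; they arise only from discretization
overshoot (the continuous dynamics preserve [0, 1]) and the neutral-Allee
clamp makes the vector field non-smooth at θ = θ_c, which is where
overshoot concentrates. Euler clips per internal step; rk45 clips sampled
output.

Degenerate inputs: an initial state that is already stationary (uniform
fixed points, frozen sub-threshold neutral-Allee states) returns a
single-sample trajectory with `t_converged = 0` rather than invoking the
integrator — this keeps "frozen" states exactly frozen, bit for bit.

## Invasion values

The invasion value of a seed node is estimated by bisection on θ_0
(default tolerance 1e-4 on the bracket width; the analyses here use 1e-3,
well below the hub/pendant contrast of ~0.3 vs ~0.01). Bisection is
justified by outcome monotonicity in θ_0, which is asserted empirically
by grid scans in the test suite and re-checked over every bisection path;
a detected violation raises rather than returning a misleading number.
Classification of "not invaded by `t_max`" as non-invaded is conservative
under that monotonicity. The horizon `t_max = 80` used for neutral-Allee
scans exceeds observed invasion completion times (~16–30) on the default
connectome several-fold; strong-Allee timing runs use `t_max = 600`
because sub-threshold decay slows the front by a factor ~20.

## Synthetic connectome generator

The generator emulates the published summary statistics of a thresholded
human structural connectome — 379 nodes, 1,738 supra-threshold links, a
hub of degree 36 with small mean shortest path, a pendant node of degree
1, full connectivity — because the underlying imaging dataset is
restricted-access. The recipe:

1. a target degree sequence: one hub (36), the requested pendants (1),
   the bulk drawn from a clipped lognormal (σ = 0.45, bounded in
   [2, hub−4]) and nudged to the exact handshake sum `2·1738`;
2. Havel–Hakimi realization, made connected by degree-preserving
   cross-component 2-edge swaps, then randomized by ~2·E connected
   double-edge swaps;
3. supra-threshold edge weights `S_w + LogNormal(ln S_w, 1)` and an equal
   number of sub-threshold noise weights `Uniform(0, S_w)` on non-edges,
   so thresholding behaves as it does on real weighted matrices.

Everything is driven by one seeded RNG stream: the same seed gives a
byte-identical matrix. The construction hits the node, link, hub and
pendant targets exactly on all seeds tested; mean shortest paths (hub
≈ 2.2–2.3, pendant ≈ 3.5–4.2) land below the reference values
(2.84 / 5.93), i.e. the synthetic topology is somewhat better mixed than
an anatomical one — it has no hemispheric or modular structure, no
geometric embedding, and no weight–distance correlation. Passing tests on
it therefore demonstrate the *mechanisms* (conservation, invasion,
hub-vs-pendant asymmetry, Allee semantics), not anatomical predictions;
on real connectomes the same asymmetries should be stronger, since longer
path lengths deepen the diffusion-dilution effect.

## Design choices

- Extremal-degree ties break toward the lowest node index, making hub and
  pendant selection deterministic even when degrees tie.
- Mean shortest path averages over the `N − 1` other nodes (unweighted
  BFS hops).
- A nonzero diagonal in `W` is rejected at load rather than silently
  zeroed; `fix_diagonal=True` (CLI `--fix-diagonal`) opts into zeroing
  with a warning. Symmetry is accepted up to `1e-12 · max(W)`.
- Node indices are 0-based in the API; files and the CLI report 1-based
  indices alongside labels and declare their index base.
- Long-format trajectory CSV by default (a 379-column wide CSV is hostile
  to downstream tools); floats serialized at 12 significant digits in
  scientific notation so byte-identical replay is meaningful.
- "Invaded" is operationalized as every node within 1e-3 of carrying
  capacity *and* all nodes above θ_c; "extinct" as `M ≤ 1e-6` (well below
  θ_0/N for any shipped configuration).

## Known limitations

- Unweighted dynamics only: the weighted Laplacian extension (per-edge
  rates) is deliberately out of scope for this version.
- No stochasticity, no nonlocal reaction coupling, no spatially varying
  `r`, `w` or `θ_c`.
- The invasion value is horizon-dependent near the transition: dynamics
  slow critically at the threshold, so a finite `t_max` biases the
  estimate slightly upward. The bracket width reported alongside the
  estimate bounds the bisection error, not this horizon bias.
- The generator matches first-order graph statistics only; it is not an
  anatomical null model.
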