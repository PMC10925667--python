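"""Summary observables of a propagation run and invasion-value estimation.

Two scalars track a trajectory through time:

* ``M(t)   = (1/N) sum_i theta_i(t)`` — mean concentration ("fraction of
  the substance in the graph"); constant under pure diffusion.
* ``N(t; theta_c) = #{i : theta_i(t) > theta_c}`` — number of nodes whose
  concentration strictly exceeds the threshold (Heaviside convention:
  a node exactly at theta_c is not counted).

The *invasion value* of a seed node is the minimal initial concentration
theta_0 injected there above which the dynamics asymptotically fill the
whole graph (M -> 1, N -> N).  It has no convenient closed form and is
estimated by bisection on theta_0, relying on the empirical monotonicity
of the outcome in theta_0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationConfig, Trajectory, integrate, point_seed
from .errors import BracketError, ValidationError
from .graph import BinaryGraph
from .reactions import ReactionSpec


@dataclass(frozen=True)
class ObservableSeries:
    """Per-time M(t) and N(t; theta_c) for one trajectory."""

    times: np.ndarray
    M: np.ndarray
    N_above: np.ndarray
    theta_c_used: float


@dataclass(frozen=True)
class Outcome:
    """Endpoint classification of a trajectory.

    ``label`` is ``invaded`` (every node at carrying capacity), ``extinct``
    (mean concentration vanished) or ``stalled`` (anything else, e.g. a
    frozen sub-threshold neutral-Allee state or the uniform diffusion
    plateau).  ``converged`` is False when the run hit t_max before the
    stationarity rule fired, in which case the label reads the final
    sampled state rather than a certified asymptotic one.
    """

    label: str
    final_M: float
    final_N_above: int
    t_converged: float | None
    converged: bool


def mean_concentration(theta) -> float:
    """Mean node concentration M = (1/N) sum_i theta_i."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValidationError("cannot average an empty concentration vector")
    return float(theta.mean())


def count_above(theta, theta_c: float) -> int:
    """Number of nodes with theta_i strictly above theta_c (Theta(0) = 0)."""
    if theta_c < 0:
        raise ValidationError(f"theta_c must be >= 0, got {theta_c!r}")
    theta = np.asarray(theta, dtype=float)
    return int(np.count_nonzero(theta - theta_c > 0))


def diffusion_limit_count(theta0_total: float, n: int, theta_c: float) -> int:
    """Large-time N(t; theta_c) under pure diffusion on a connected graph.

    Diffusion spreads the initial mass uniformly, so every node ends at
    theta0_total / n: the count is ``n`` when that exceeds theta_c and 0
    otherwise (the boundary case falls on the 0 side).
    """
    if n < 1:
        raise ValidationError("node count n must be >= 1")
    return n if theta0_total / n > theta_c else 0


def observable_series(traj: Trajectory, theta_c: float) -> ObservableSeries:
    """Compute M(t) and N(t; theta_c) along a trajectory."""
    M = traj.states.mean(axis=1)
    N_above = np.count_nonzero(traj.states - theta_c > 0, axis=1)
    return ObservableSeries(
        times=traj.times, M=M, N_above=N_above.astype(int), theta_c_used=float(theta_c)
    )


def classify_outcome(
    traj: Trajectory,
    theta_c: float,
    tol_extinct: float = 1e-6,
    tol_invaded: float = 1e-3,
) -> Outcome:
    """Classify a trajectory endpoint as invaded / extinct / stalled.

    Invasion requires every node within ``tol_invaded`` of carrying
    capacity *and* all nodes above theta_c; extinction requires the mean
    concentration below ``tol_extinct``.
    """
    theta = traj.final_state
    M = mean_concentration(theta)
    n_above = count_above(theta, theta_c)
    if n_above == traj.n_nodes and theta.min() >= 1.0 - tol_invaded:
        label = "invaded"
    elif M <= tol_extinct:
        label = "extinct"
    else:
        label = "stalled"
    return Outcome(
        label=label,
        final_M=M,
        final_N_above=n_above,
        t_converged=traj.t_converged,
        converged=traj.converged,
    )


def time_to_invasion(traj: Trajectory, tol_invaded: float = 1e-3) -> float | None:
    """First sampled time with every node within tol_invaded of capacity."""
    full = np.nonzero(traj.states.min(axis=1) >= 1.0 - tol_invaded)[0]
    return float(traj.times[full[0]]) if full.size else None


@dataclass(frozen=True)
class InvasionEstimate:
    """Bisection result: midpoint estimate plus the final bracket."""

    value: float
    bracket_lo: float
    bracket_hi: float
    seed_node: int
    n_simulations: int


def _invades(
    G: BinaryGraph,
    spec: ReactionSpec,
    config: SimulationConfig,
    seed_node: int,
    theta0: float,
    tol_invaded: float,
) -> bool:
    if theta0 <= 0:
        return False
    traj = integrate(G, spec, config, point_seed(G.n_nodes, seed_node, theta0))
    return classify_outcome(traj, spec.theta_c, tol_invaded=tol_invaded).label == "invaded"


def invasion_value(
    G: BinaryGraph,
    spec: ReactionSpec,
    config: SimulationConfig,
    seed_node: int,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-4,
    tol_invaded: float = 1e-3,
) -> InvasionEstimate:
    """Estimate the invasion value of ``seed_node`` by bisection on theta_0.

    ``bracket = (lo, hi)`` must straddle the transition: the run seeded
    with ``lo`` must not invade and the run seeded with ``hi`` must.  The
    default bracket is ``(theta_c / 10, 1)`` (with lo = 0 meaning "no
    simulation needed; an empty network stays empty").  Bisection assumes
    the outcome is monotone in theta_0; the evaluated points are checked
    for consistency and a violation raises.
    """
    if bracket is None:
        bracket = (spec.theta_c / 10.0, 1.0)
    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0 <= lo < hi):
        raise BracketError(f"invalid bracket [{lo}, {hi}]")
    history: list[tuple[float, bool]] = []

    def probe(theta0: float) -> bool:
        inv = _invades(G, spec, config, seed_node, theta0, tol_invaded)
        history.append((theta0, inv))
        return inv

    if probe(lo):
        raise BracketError(
            f"lower bracket edge theta0 = {lo} already invades; "
            "widen the bracket downward"
        )
    if not probe(hi):
        raise BracketError(
            f"upper bracket edge theta0 = {hi} does not invade; "
            "widen the bracket upward (or the dynamics never invade)"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if probe(mid):
            hi = mid
        else:
            lo = mid
    history.sort()
    flags = [inv for _, inv in history]
    if any(a and not b for a, b in zip(flags, flags[1:])):
        bad = [(t, inv) for t, inv in history]
        raise BracketError(
            f"outcome is not monotone in theta0 along the bisection path: {bad}"
        )
    return InvasionEstimate(
        value=0.5 * (lo + hi),
        bracket_lo=lo,
        bracket_hi=hi,
        seed_node=seed_node,
        n_simulations=len(history),
    )
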