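"""Local reaction terms g(theta) for growth/decay of concentration in a node.

All three kinds share the homogeneous fixed points theta = 0 and theta = 1
(carrying capacity normalized to 1):

* ``logistic``       g(t) = t (1 - t)                 — FKPP growth; any
  positive concentration is amplified.
* ``strong_allee``   g(t) = t (t - t_c) (1 - t)       — per-capita rate is
  negative below the Allee threshold t_c, so sub-threshold states decay.
* ``neutral_allee``  g(t) = max((t - t_c)(1 - t), 0)  — growth is switched
  off (exactly zero) below t_c; sub-threshold states are frozen.
* ``none``           g = 0                            — pure diffusion.

The registry is extensible: new kinds register a ``(theta, theta_c) ->
rate`` callable under a name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ConfigurationError

ReactionFn = Callable[[np.ndarray, float], np.ndarray]


def g_logistic(theta):
    """Logistic growth theta * (1 - theta)."""
    theta = np.asarray(theta, dtype=float)
    return theta * (1.0 - theta)


def g_strong_allee(theta, theta_c: float):
    """Strong Allee term theta * (theta - theta_c) * (1 - theta).

    Negative on (0, theta_c), positive on (theta_c, 1); roots at 0,
    theta_c and 1.
    """
    theta = np.asarray(theta, dtype=float)
    return theta * (theta - theta_c) * (1.0 - theta)


def g_neutral_allee(theta, theta_c: float):
    """Neutral Allee term max((theta - theta_c) * (1 - theta), 0).

    Exactly zero for theta <= theta_c: sub-threshold concentration
    neither grows nor decays through the reaction.
    """
    theta = np.asarray(theta, dtype=float)
    return np.maximum((theta - theta_c) * (1.0 - theta), 0.0)


_REGISTRY: dict[str, ReactionFn] = {
    "logistic": lambda t, tc: g_logistic(t),
    "strong_allee": g_strong_allee,
    "neutral_allee": g_neutral_allee,
    "none": lambda t, tc: np.zeros_like(np.asarray(t, dtype=float)),
}

REACTION_KINDS = tuple(_REGISTRY)


def register_reaction(name: str, fn: ReactionFn) -> None:
    """Register a new reaction kind under ``name``.

    ``fn(theta, theta_c)`` must return an array of the same shape; for the
    homogeneous states to stay stationary it should satisfy
    ``fn(0) = fn(1) = 0``.
    """
    _REGISTRY[str(name)] = fn


@dataclass(frozen=True)
class ReactionSpec:
    """Reaction kind plus rate ``r`` and Allee threshold ``theta_c``.

    ``theta_c`` is ignored by the logistic and ``none`` kinds.  Defaults
    follow the reference parameterization r = 1, theta_c = 0.001.
    """

    kind: str = "logistic"
    r: float = 1.0
    theta_c: float = 0.001

    def __post_init__(self) -> None:
        if self.kind not in _REGISTRY:
            raise ConfigurationError(
                f"unknown reaction kind {self.kind!r}; "
                f"known kinds: {sorted(_REGISTRY)}"
            )
        if not (self.r > 0):
            raise ConfigurationError(f"reaction rate r must be > 0, got {self.r!r}")
        if not (0.0 <= self.theta_c < 1.0):
            raise ConfigurationError(
                f"Allee threshold theta_c must lie in [0, 1), got {self.theta_c!r}"
            )

    def g(self, theta) -> np.ndarray:
        """Evaluate the bare reaction term g(theta), without the rate r."""
        return _REGISTRY[self.kind](np.asarray(theta, dtype=float), self.theta_c)


def evaluate(spec: ReactionSpec, theta) -> np.ndarray:
    """Elementwise reaction contribution r * g(theta_i) for a state vector."""
    return spec.r * spec.g(theta)
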