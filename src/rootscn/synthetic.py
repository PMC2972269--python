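"""Seeded random Boolean networks (NK ensemble) and the annealed Derrida oracle.

The classical NK random Boolean network — every node gets K distinct
inputs drawn uniformly (self-inputs allowed) and an independent random
truth table with output bias p — has a closed-form expected Derrida map
under the annealed approximation:

    H(t+1) = 2 p (1-p) * [1 - (1 - H(t))**K],

with slope 2 K p (1-p) at the origin: < 1 ordered, = 1 critical, > 1
chaotic.  These ensembles exercise every engine component (generation,
stepping, attractor search, Derrida sampling) against known statistics,
with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkError, NetworkModel, RuleTable, build_network
from .perturbation import derrida_map

__all__ = [
    "RandomNetSpec",
    "random_network",
    "annealed_derrida",
    "annealed_derrida_curve",
    "derrida_ensemble_check",
]


@dataclass(frozen=True)
class RandomNetSpec:
    """Parameters of one NK random Boolean network draw."""

    N: int
    K: int
    p: float
    seed: int

    def __post_init__(self):
        if self.N < 1:
            raise NetworkError("N must be >= 1")
        if not 0 <= self.K <= self.N:
            raise NetworkError(f"K must satisfy 0 <= K <= N, got K={self.K}, N={self.N}")
        if not 0.0 <= self.p <= 1.0:
            raise NetworkError(f"bias p must lie in [0,1], got {self.p}")


def random_network(spec: RandomNetSpec) -> NetworkModel:
    """Draw one NK network; identical spec (incl. seed) => identical model.

    Inputs are sampled without replacement per node (self-inputs
    allowed); every truth-table row outputs 1 independently with
    probability p.
    """
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"n{i}" for i in range(spec.N))
    rules = []
    for name in names:
        inputs = tuple(names[j] for j in sorted(rng.choice(spec.N, size=spec.K, replace=False)))
        outputs = (rng.random(2**spec.K) < spec.p).astype(np.uint8)
        rules.append(RuleTable(name, inputs, outputs))
    return build_network(names, rules)


def annealed_derrida(h: np.ndarray | float, K: int, p: float):
    """Annealed-approximation expected H(t+1) for initial distance H(t)=h."""
    h = np.asarray(h, dtype=float)
    return 2.0 * p * (1.0 - p) * (1.0 - (1.0 - h) ** K)


def annealed_derrida_curve(K: int, p: float, distances=None) -> dict[float, float]:
    """The annealed map tabulated at normalised distance classes."""
    if distances is None:
        distances = np.linspace(0.0, 1.0, 21)
    return {float(d): float(annealed_derrida(d, K, p)) for d in np.asarray(distances, float)}


def exact_flip_propagation(N: int, K: int, d: int, p: float) -> float:
    """Exact expected H(t+1) for this ensemble at absolute distance d.

    With K inputs drawn without replacement and exactly d bits flipped,
    a node's input row changes with probability 1 - C(N-d,K)/C(N,K)
    (hypergeometric), and a changed row redraws the output, differing
    with probability 2p(1-p).  The annealed formula replaces the
    hypergeometric factor with its with-replacement limit
    1-(1-d/N)**K, which it approaches as N grows.
    """
    from math import comb

    if d == 0:
        return 0.0
    hit = 1.0 - (comb(N - d, K) / comb(N, K) if d <= N - K else 0.0)
    return 2.0 * p * (1.0 - p) * hit


@dataclass
class DerridaEnsembleResult:
    """Per-class comparison of empirical and closed-form Derrida values."""

    distances: np.ndarray        # normalised H(t)
    empirical: np.ndarray        # grand mean H(t+1) over networks
    stderr: np.ndarray           # standard error across networks
    expected: np.ndarray         # exact same-ensemble closed form
    annealed: np.ndarray         # annealed (large-N) closed form

    @property
    def max_sigma(self) -> float:
        """Largest |empirical - expected| in standard-error units."""
        return float(np.max(np.abs(self.empirical - self.expected) / self.stderr))


def derrida_ensemble_check(
    N: int = 30,
    K: int = 2,
    p: float = 0.5,
    n_networks: int = 100,
    pairs_per_class: int = 100,
    distances: tuple[int, ...] = (1, 2, 3, 5, 8, 15, 30),
    seed: int = 0,
) -> DerridaEnsembleResult:
    """Empirical Derrida means over an NK ensemble vs the closed forms.

    For each of ``n_networks`` seeded networks the empirical Derrida map
    is sampled at the given absolute distance classes; the standard
    error is taken across networks, so quenched network-to-network
    variability is part of the error bar.  The comparison oracle is the
    exact without-replacement expectation
    (:func:`exact_flip_propagation`); the annealed curve is reported
    alongside as its large-N limit.
    """
    rng = np.random.default_rng(seed)
    per_net = np.zeros((n_networks, len(distances)))
    for i in range(n_networks):
        net = random_network(RandomNetSpec(N=N, K=K, p=p, seed=int(rng.integers(2**31))))
        curve = derrida_map(
            net, n_pairs=pairs_per_class, seed=int(rng.integers(2**31)), distances=distances
        )
        per_net[i] = [curve.points[d / N] for d in distances]
    emp = per_net.mean(axis=0)
    se = per_net.std(axis=0, ddof=1) / np.sqrt(n_networks)
    d_norm = np.array([d / N for d in distances])
    return DerridaEnsembleResult(
        distances=d_norm,
        empirical=emp,
        stderr=se,
        expected=np.array([exact_flip_propagation(N, K, d, p) for d in distances]),
        annealed=annealed_derrida(d_norm, K, p),
    )
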