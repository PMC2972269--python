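"""Mutant simulation, rule-perturbation robustness, and Derrida analysis.

Three complementary robustness probes of a Boolean network:

* **Mutants** — clamp one node to 0 (loss of function) or 1 (gain of
  function) from t=0 onward and recompute the exhaustive attractor set.
* **Rule-flip scan** — flip every output bit of every truth table, one
  at a time, and ask whether the attractor set survives unchanged.  The
  comparison looks only at the set of attractor states, not at basin
  sizes.
* **Derrida map** — for pairs of states at a controlled Hamming
  distance, the mean distance after one synchronous step.  A curve that
  hugs the identity line at small distances is the signature of critical
  (neither ordered nor chaotic) dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    AttractorSet,
    NetworkError,
    NetworkModel,
    batch_step,
    clamp,
    find_attractors,
)

__all__ = [
    "MutantSpec",
    "FlipResult",
    "RobustnessSummary",
    "DerridaCurve",
    "simulate_mutant",
    "rule_flip_scan",
    "derrida_map",
]


@dataclass(frozen=True)
class MutantSpec:
    """A single-gene perturbation: loss clamps to 0, gain clamps to 1."""

    node: str
    kind: str  # "loss" | "gain"

    def __post_init__(self):
        if self.kind not in ("loss", "gain"):
            raise NetworkError(f"mutant kind must be 'loss' or 'gain', got {self.kind!r}")

    @property
    def clamp_value(self) -> int:
        return 0 if self.kind == "loss" else 1


def simulate_mutant(model: NetworkModel, spec: MutantSpec) -> AttractorSet:
    """Exhaustive attractor set of the clamped model.

    The clamp overrides the node's rule at every step and replaces its
    value in the initial condition.
    """
    if spec.node not in model.node_index:
        raise NetworkError(f"unknown node {spec.node!r}")
    return find_attractors(clamp(model, spec.node, spec.clamp_value), mode="exhaustive")


@dataclass(frozen=True)
class FlipResult:
    node: str
    row: int
    changed: bool


@dataclass
class RobustnessSummary:
    """Outcome of the single-output rule-flip scan."""

    total_flips: int
    unchanged: int
    changed: int
    fraction_unchanged: float
    flips: list[FlipResult] = field(default_factory=list, repr=False)


def rule_flip_scan(model: NetworkModel, cap: int = 16) -> RobustnessSummary:
    """Flip every truth-table output bit once and reclassify attractors.

    There are sum_n 2**(k_n) flips.  A flip counts as "unchanged" iff
    the exhaustive attractor state set of the altered network equals the
    wild-type set exactly (no novel attractors, none lost); each bit is
    restored before the next flip.
    """
    if model.n > cap:
        raise NetworkError(f"rule_flip_scan needs exhaustive search; N={model.n} > {cap}")
    wild = find_attractors(model, mode="exhaustive").states_set()
    flips: list[FlipResult] = []
    unchanged = 0
    for rule in model.rules:
        for row in range(len(rule.outputs)):
            flipped = model.with_rule(rule.with_flipped_output(row))
            same = find_attractors(flipped, mode="exhaustive").states_set() == wild
            flips.append(FlipResult(rule.target, row, changed=not same))
            unchanged += int(same)
    total = len(flips)
    return RobustnessSummary(
        total_flips=total,
        unchanged=unchanged,
        changed=total - unchanged,
        fraction_unchanged=unchanged / total,
        flips=flips,
    )


@dataclass
class DerridaCurve:
    """Mean one-step Hamming distance response, per initial distance class.

    ``points`` maps the normalised initial distance H(t) = d/N to the
    mean normalised distance after one synchronous step.
    """

    points: dict[float, float]
    n_pairs: int
    seed: int

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.array(sorted(self.points))
        return d, np.array([self.points[x] for x in d])


def derrida_map(
    model: NetworkModel,
    n_pairs: int = 10_000,
    seed: int = 0,
    distances: tuple[int, ...] | None = None,
) -> DerridaCurve:
    """Empirical Derrida map of a network.

    For every initial Hamming distance d in ``distances`` (default
    1..N), draw ``n_pairs`` seeded random states, flip exactly d
    distinct bits of each to form the partner, advance both one
    synchronous step, and record the mean normalised distance.  The
    degenerate class d=0 is included analytically (determinism maps it
    to 0).
    """
    if n_pairs < 1:
        raise NetworkError("n_pairs must be >= 1")
    n = model.n
    if distances is None:
        distances = tuple(range(1, n + 1))
    rng = np.random.default_rng(seed)
    points: dict[float, float] = {0.0: 0.0}
    for d in distances:
        if not 1 <= d <= n:
            raise NetworkError(f"distance {d} outside 1..{n}")
        states = rng.integers(0, 2**n, size=n_pairs, dtype=np.uint64)
        # choose exactly d distinct bit positions per pair
        scores = rng.random((n_pairs, n))
        picked = np.argpartition(scores, d - 1, axis=1)[:, :d]
        masks = np.bitwise_or.reduce(
            np.uint64(1) << picked.astype(np.uint64), axis=1
        )
        partners = states ^ masks
        h1 = np.bitwise_count(batch_step(model, states) ^ batch_step(model, partners))
        points[d / n] = float(h1.mean() / n)
    return DerridaCurve(points=points, n_pairs=n_pairs, seed=seed)
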