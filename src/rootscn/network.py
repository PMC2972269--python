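"""Deterministic synchronous Boolean network engine.

A network is a list of named nodes, one truth table per node, and an
optional set of clamps (nodes held at a constant value, as in loss- or
gain-of-function simulations).  All nodes are updated simultaneously:

    x_n(t+1) = F_n(x_{n_1}(t), ..., x_{n_k}(t))

States are length-N 0/1 vectors.  Internally a state is packed into a
single integer with node 0 in the most significant bit, so the integer
order of states equals the lexicographic order of their bit vectors and
exhaustive sweeps over all 2**N initial conditions vectorise cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import expr as ex

__all__ = [
    "NetworkError",
    "RuleTable",
    "NetworkModel",
    "Attractor",
    "AttractorSet",
    "Trajectory",
    "build_network",
    "sync_step",
    "clamp",
    "batch_step",
    "transition_table",
    "trajectory",
    "find_attractors",
]

#: exhaustive search refuses networks larger than this by default
EXHAUSTIVE_CAP = 24


class NetworkError(ValueError):
    """Raised on malformed networks, rules or states."""


class RuleTable:
    """Truth table of one node's update function.

    Parameters
    ----------
    target:
        Name of the regulated node.
    inputs:
        Ordered regulator names; arity k may be 0 (a constant node).
    outputs:
        2**k Boolean outputs.  Row ``r`` corresponds to the input pattern
        whose bits, most-significant-first in the declared input order,
        spell ``r`` (row 0 = all inputs off, row 2**k - 1 = all on).
    expression:
        Optional source expression the table was built from; retained for
        lossless rule-file round trips and for the continuous conversion.
    """

    __slots__ = ("target", "inputs", "outputs", "expression")

    def __init__(
        self,
        target: str,
        inputs: Sequence[str],
        outputs: Sequence[int] | np.ndarray,
        expression: ex.Expr | None = None,
    ):
        self.target = str(target)
        self.inputs = tuple(str(i) for i in inputs)
        out = np.asarray(outputs, dtype=np.uint8)
        if out.ndim != 1 or len(out) != 2 ** len(self.inputs):
            raise NetworkError(
                f"rule for {target!r}: expected {2 ** len(self.inputs)} outputs, "
                f"got {out.size}"
            )
        if not np.isin(out, (0, 1)).all():
            raise NetworkError(f"rule for {target!r}: outputs must be 0/1")
        out.setflags(write=False)
        self.outputs = out
        self.expression = expression

    @classmethod
    def from_expression(
        cls,
        target: str,
        expression: str | ex.Expr,
        inputs: Sequence[str] | None = None,
    ) -> "RuleTable":
        """Build a table from a logic expression.

        ``inputs`` fixes the declared input order (and may include inputs
        the expression does not mention, keeping a uniform arity across
        model variants); by default inputs are the expression's variables
        in order of first appearance.
        """
        node = ex.parse(expression) if isinstance(expression, str) else expression
        ins = tuple(inputs) if inputs is not None else ex.variables(node)
        return cls(target, ins, ex.truth_table(node, ins), expression=node)

    @property
    def arity(self) -> int:
        return len(self.inputs)

    def as_expression(self) -> ex.Expr:
        """Source expression if available, else the minterm DNF."""
        if self.expression is not None:
            return self.expression
        return ex.dnf_from_table(self.inputs, self.outputs)

    def with_flipped_output(self, row: int) -> "RuleTable":
        """Copy of the rule with one output bit inverted (0-based row)."""
        out = self.outputs.copy()
        out[row] ^= 1
        return RuleTable(self.target, self.inputs, out)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RuleTable)
            and self.target == other.target
            and self.inputs == other.inputs
            and bool(np.array_equal(self.outputs, other.outputs))
        )

    def __repr__(self) -> str:
        bits = "".join(map(str, self.outputs))
        return f"RuleTable({self.target!r}, inputs={self.inputs}, outputs={bits!r})"


class NetworkModel:
    """Immutable synchronous Boolean network.

    ``clamps`` maps node names to forced constant values; a clamped node
    ignores its rule at every step and its clamp also overrides the
    initial condition of any trajectory.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        rules: Iterable[RuleTable],
        clamps: Mapping[str, int] | None = None,
    ):
        self.nodes: tuple[str, ...] = tuple(str(n) for n in nodes)
        if len(set(self.nodes)) != len(self.nodes):
            dup = sorted({n for n in self.nodes if self.nodes.count(n) > 1})
            raise NetworkError(f"duplicate node names: {dup}")
        self.node_index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}

        by_target: dict[str, RuleTable] = {}
        for rule in rules:
            if rule.target not in self.node_index:
                raise NetworkError(f"rule targets undeclared node {rule.target!r}")
            if rule.target in by_target:
                raise NetworkError(f"duplicate rule for node {rule.target!r}")
            for inp in rule.inputs:
                if inp not in self.node_index:
                    raise NetworkError(
                        f"rule for {rule.target!r} references undeclared node {inp!r}"
                    )
            by_target[rule.target] = rule
        missing = [n for n in self.nodes if n not in by_target]
        if missing:
            raise NetworkError(f"missing rules for nodes: {missing}")
        self.rules: tuple[RuleTable, ...] = tuple(by_target[n] for n in self.nodes)

        self.clamps: dict[str, int] = {}
        for name, value in (clamps or {}).items():
            if name not in self.node_index:
                raise NetworkError(f"cannot clamp unknown node {name!r}")
            if value not in (0, 1):
                raise NetworkError(f"clamp value for {name!r} must be 0 or 1")
            self.clamps[name] = int(value)

        self._compile()

    # -- compiled representation -------------------------------------------------
    def _compile(self) -> None:
        n = self.n
        self._shifts = [
            np.array(
                [np.uint64(n - 1 - self.node_index[i]) for i in rule.inputs],
                dtype=np.uint64,
            )
            for rule in self.rules
        ]
        self._tables = [rule.outputs.astype(np.uint64) for rule in self.rules]
        mask = 0
        bits = 0
        for name, value in self.clamps.items():
            b = 1 << (n - 1 - self.node_index[name])
            mask |= b
            if value:
                bits |= b
        self._clamp_mask = np.uint64(mask)
        self._clamp_bits = np.uint64(bits)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def space_size(self) -> int:
        return 2**self.n

    # -- state packing -----------------------------------------------------------
    def encode(self, state: Sequence[int]) -> int:
        if len(state) != self.n:
            raise NetworkError(f"state length {len(state)} != N = {self.n}")
        value = 0
        for i, bit in enumerate(state):
            if bit not in (0, 1):
                raise NetworkError("state entries must be 0 or 1")
            if bit:
                value |= 1 << (self.n - 1 - i)
        return value

    def decode(self, value: int) -> tuple[int, ...]:
        return tuple((int(value) >> (self.n - 1 - i)) & 1 for i in range(self.n))

    def apply_clamps(self, value: int) -> int:
        return (int(value) & ~int(self._clamp_mask)) | int(self._clamp_bits)

    # -- derived models ----------------------------------------------------------
    def with_clamp(self, node: str, value: int) -> "NetworkModel":
        clamps = dict(self.clamps)
        clamps[node] = value
        return NetworkModel(self.nodes, self.rules, clamps)

    def with_rule(self, rule: RuleTable) -> "NetworkModel":
        rules = [rule if r.target == rule.target else r for r in self.rules]
        return NetworkModel(self.nodes, rules, self.clamps)

    def __repr__(self) -> str:
        return f"NetworkModel(N={self.n}, nodes={self.nodes}, clamps={self.clamps})"


@dataclass(frozen=True)
class Attractor:
    """A fixed point (period 1) or cycle of the synchronous map.

    ``states`` is rotated so the lexicographically smallest state comes
    first, giving every attractor a unique canonical representative.
    """

    states: tuple[tuple[int, ...], ...]
    period: int
    label: str | None = None

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def key(self) -> tuple[tuple[int, ...], ...]:
        return self.states

    def with_label(self, label: str | None) -> "Attractor":
        return Attractor(self.states, self.period, label)


@dataclass
class AttractorSet:
    """Attractors plus basin bookkeeping for an explored state space."""

    attractors: list[Attractor]
    basin_counts: list[int]
    space_size: int
    mode: str  # "exhaustive" | "sampled"
    seed: int | None = None
    assignments: np.ndarray | None = field(default=None, repr=False)

    def states_set(self) -> frozenset:
        return frozenset(a.key() for a in self.attractors)

    def fixed_points(self) -> list[tuple[int, ...]]:
        return [a.states[0] for a in self.attractors if a.is_fixed_point]

    def labels(self) -> list[str | None]:
        return [a.label for a in self.attractors]

    def __len__(self) -> int:
        return len(self.attractors)


@dataclass(frozen=True)
class Trajectory:
    states: tuple[tuple[int, ...], ...]
    transient_length: int
    attractor: Attractor


# -- public operations -----------------------------------------------------------


def build_network(
    nodes: Sequence[str],
    rules: Iterable[RuleTable],
    clamps: Mapping[str, int] | None = None,
) -> NetworkModel:
    """Construct and validate a synchronous Boolean network."""
    return NetworkModel(nodes, rules, clamps)


def clamp(model: NetworkModel, node: str, value: int) -> NetworkModel:
    """Hold ``node`` at ``value`` at every step, including t=0."""
    return model.with_clamp(node, value)


def batch_step(model: NetworkModel, states: np.ndarray) -> np.ndarray:
    """Synchronous update of an array of packed states (vectorised)."""
    states = np.asarray(states, dtype=np.uint64)
    nxt = np.zeros_like(states)
    n = model.n
    one = np.uint64(1)
    for i in range(n):
        shifts = model._shifts[i]
        k = len(shifts)
        if k:
            rows = np.zeros_like(states)
            for j in range(k):
                rows = (rows << one) | ((states >> shifts[j]) & one)
            bits = model._tables[i][rows]
        else:
            bits = np.full_like(states, model._tables[i][0])
        nxt |= bits << np.uint64(n - 1 - i)
    nxt &= ~model._clamp_mask
    nxt |= model._clamp_bits
    return nxt


def step_int(model: NetworkModel, state: int) -> int:
    """Single-state synchronous update on packed integers."""
    return int(batch_step(model, np.array([state], dtype=np.uint64))[0])


def sync_step(model: NetworkModel, state: Sequence[int]) -> tuple[int, ...]:
    """One synchronous update of a bit-vector state.

    Clamped nodes take their clamp value; all others take their rule's
    output evaluated on the time-t state.
    """
    return model.decode(step_int(model, model.encode(state)))


def transition_table(model: NetworkModel, cap: int = EXHAUSTIVE_CAP) -> np.ndarray:
    """Packed successor of every state in the 2**N space."""
    if model.n > cap:
        raise NetworkError(
            f"N={model.n} exceeds the exhaustive cap ({cap}); use sampled mode"
        )
    states = np.arange(model.space_size, dtype=np.uint64)
    return batch_step(model, states)


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Rotate a cycle so its smallest state comes first."""
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def _attractor_from_ints(model: NetworkModel, cycle: tuple[int, ...]) -> Attractor:
    return Attractor(tuple(model.decode(s) for s in cycle), period=len(cycle))


def trajectory(model: NetworkModel, state: Sequence[int] | int) -> Trajectory:
    """Iterate from ``state`` until the attractor is entered.

    The trajectory records the visited states from the (clamp-adjusted)
    initial condition up to and including one full traversal of the
    attractor; determinism guarantees termination within 2**N steps.
    """
    s = state if isinstance(state, (int, np.integer)) else model.encode(state)
    s = model.apply_clamps(int(s))
    seen: dict[int, int] = {}
    path: list[int] = []
    while s not in seen:
        seen[s] = len(path)
        path.append(s)
        s = step_int(model, s)
    start = seen[s]
    cycle = _canonical_cycle(path[start:])
    states = tuple(model.decode(x) for x in path)
    return Trajectory(states, transient_length=start, attractor=_attractor_from_ints(model, cycle))


def _exhaustive_attractors(model: NetworkModel, cap: int) -> AttractorSet:
    n = model.n
    size = model.space_size
    T = transition_table(model, cap=cap)
    # f^(2**N) by repeated squaring: every state lands on its attractor.
    F = T.copy()
    for _ in range(n):
        F = F[F]
    # Clamps replace the initial value too: state s starts from clamp(s).
    starts = (np.arange(size, dtype=np.uint64) & ~model._clamp_mask) | model._clamp_bits
    F = F[starts]
    reps = np.unique(F)
    cycles: list[tuple[int, ...]] = []
    on_cycle: dict[int, int] = {}
    for rep in reps.tolist():
        if rep in on_cycle:
            continue
        cyc = [rep]
        s = int(T[rep])
        while s != rep:
            cyc.append(s)
            s = int(T[s])
        cyc = list(_canonical_cycle(cyc))
        idx = len(cycles)
        cycles.append(tuple(cyc))
        for x in cyc:
            on_cycle[x] = idx
    order = np.argsort([c[0] for c in cycles], kind="stable")
    cycles = [cycles[i] for i in order]
    on_cycle = {x: i for i, cyc in enumerate(cycles) for x in cyc}
    cyc_states = np.array(sorted(on_cycle), dtype=np.uint64)
    cyc_ids = np.array([on_cycle[int(s)] for s in cyc_states], dtype=np.int64)
    assignments = cyc_ids[np.searchsorted(cyc_states, F)]
    counts = np.bincount(assignments, minlength=len(cycles))
    attractors = [_attractor_from_ints(model, c) for c in cycles]
    return AttractorSet(
        attractors=attractors,
        basin_counts=[int(c) for c in counts],
        space_size=size,
        mode="exhaustive",
        assignments=assignments,
    )


def _sampled_attractors(model: NetworkModel, n_samples: int, seed: int) -> AttractorSet:
    rng = np.random.default_rng(seed)
    if model.n <= 62:
        samples = rng.integers(0, model.space_size, size=n_samples, dtype=np.uint64)
    else:  # pragma: no cover - engine cap is far below this
        raise NetworkError("sampled mode supports at most 62 nodes")
    memo: dict[int, int] = {}
    cycles: list[tuple[int, ...]] = []
    counts: list[int] = []
    for s0 in samples.tolist():
        s = model.apply_clamps(int(s0))
        path: list[int] = []
        pos: dict[int, int] = {}
        while s not in memo and s not in pos:
            pos[s] = len(path)
            path.append(s)
            s = step_int(model, s)
        if s in memo:
            idx = memo[s]
        else:
            cyc = _canonical_cycle(path[pos[s]:])
            try:
                idx = cycles.index(cyc)
            except ValueError:
                idx = len(cycles)
                cycles.append(cyc)
                counts.append(0)
        for x in path:
            memo[x] = idx
        counts[idx] += 1
    attractors = [_attractor_from_ints(model, c) for c in cycles]
    return AttractorSet(
        attractors=attractors,
        basin_counts=counts,
        space_size=n_samples,
        mode="sampled",
        seed=seed,
    )


def find_attractors(
    model: NetworkModel,
    mode: str = "exhaustive",
    n_samples: int | None = None,
    seed: int | None = None,
    cap: int = EXHAUSTIVE_CAP,
) -> AttractorSet:
    """Attractors and basin counts of the explored initial conditions.

    Exhaustive mode sweeps all 2**N initial states (N <= ``cap``);
    sampled mode draws ``n_samples`` seeded uniform initial states.
    Cycles of any period are detected; basin counts sum to the number of
    explored initial states.
    """
    if mode == "exhaustive":
        return _exhaustive_attractors(model, cap)
    if mode == "sampled":
        if n_samples is None or n_samples < 1:
            raise NetworkError("sampled mode requires n_samples >= 1")
        if seed is None:
            raise NetworkError("sampled mode requires an explicit seed")
        return _sampled_attractors(model, int(n_samples), int(seed))
    raise NetworkError(f"unknown mode {mode!r}")
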