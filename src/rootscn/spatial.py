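"""Four-cell coupled meta-GRN of the root stem-cell niche.

Four positional cells — V (vascular initials), C (cortex/endodermis
initials), Q (quiescent centre) and E (columella/epidermis initials) —
each run the single-cell B' network, with the rules of the mobile
regulators SHR, auxin, WOX5 and CLEX augmented by neighbour terms:

* SHR is transcribed only in V (clamped on there) and moves into a cell
  from any neighbour where it is present and SCR is absent (SCR traps
  SHR in the nucleus, blocking onward movement);
* auxin is supplied from above (clamped on in V and C) and flows
  acropetally V/C -> Q -> E;
* WOX5 acts locally in the QC as the activator of an activator-inhibitor
  motif (enhancing auxin signalling by repressing Aux/IAA) and activates
  its own long-range inhibitor CLEX in every cell *except* the QC;
* CLEX diffuses: its repression of WOX5 reads the OR over all cells.

SCR cannot be transcribed in V — the only topological change relative to
the single-cell model.  Because SCR requires itself, simulations use an
initialisation convention: SCR is held on in every (non-V) cell at t=0
and t=1, standing in for the basal expression a Boolean model cannot
represent, and follows its own rule from t=2 on.

With that convention every initial condition converges to a single
global fixed point whose per-cell projections are the four cell-type
profiles; the continuous (logistic ODE) version reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .continuous import ContinuousModel, integrate_batch, to_continuous
from .models import NODES_B, reference_profiles
from .network import (
    Attractor,
    AttractorSet,
    NetworkError,
    NetworkModel,
    RuleTable,
    Trajectory,
    build_network,
    batch_step,
    step_int,
    trajectory as _trajectory,
)

__all__ = [
    "CELLS",
    "MobilitySpec",
    "MetaGRN",
    "SpatialPattern",
    "build_meta_grn",
    "run_spatial",
    "find_global_attractors",
    "simulate_spatial_mutant",
    "continuous_spatial_attractors",
]

#: positional cells, one per single-cell attractor
CELLS = ("V", "C", "Q", "E")

#: expected wild-type cell fate at each position
EXPECTED_FATE = {"V": "vascular", "C": "CEI", "Q": "QC", "E": "CEpI"}

MOBILE_NODES = ("SHR", "Auxin", "WOX5", "CLEX")

_DEFAULT_ADJACENCY = frozenset(
    {frozenset({"V", "Q"}), frozenset({"V", "C"}), frozenset({"C", "Q"}), frozenset({"Q", "E"})}
)


@dataclass(frozen=True)
class MobilitySpec:
    """Cell adjacency and the set of mobile regulators.

    The adjacency (root anatomy: vascular above the QC, CEI lateral,
    columella initials below) gates SHR movement; auxin follows the
    fixed acropetal route V/C -> Q -> E; WOX5 and CLEX act over the
    whole niche.  Mobility is fixed for the entire run.
    """

    adjacency: frozenset = _DEFAULT_ADJACENCY
    mobile: tuple[str, ...] = MOBILE_NODES

    def __post_init__(self):
        for pair in self.adjacency:
            if not (isinstance(pair, frozenset) and len(pair) == 2 and pair <= set(CELLS)):
                raise NetworkError(f"malformed adjacency entry {set(pair)!r}")
        if set(self.mobile) != set(MOBILE_NODES):
            raise NetworkError(
                f"mobile nodes must be exactly {MOBILE_NODES}; their movement "
                "semantics are part of the model definition"
            )

    def neighbours(self, cell: str) -> tuple[str, ...]:
        return tuple(c for c in CELLS if c != cell and frozenset({c, cell}) in self.adjacency)


def _var(node: str, cell: str) -> str:
    return f"{node}@{cell}"


@dataclass
class MetaGRN:
    """40-variable coupled model: 10 intracellular nodes x 4 cells."""

    network: NetworkModel
    mobility: MobilitySpec
    cells: tuple[str, ...] = CELLS
    cell_nodes: tuple[str, ...] = NODES_B

    def var(self, node: str, cell: str) -> str:
        return _var(node, cell)

    def cell_indices(self, cell: str) -> list[int]:
        return [self.network.node_index[_var(n, cell)] for n in self.cell_nodes]

    def project(self, state: tuple[int, ...], cell: str) -> tuple[int, ...]:
        return tuple(state[i] for i in self.cell_indices(cell))

    @property
    def scr_free_vars(self) -> list[str]:
        """SCR variables subject to the initialisation convention."""
        return [
            _var("SCR", c)
            for c in self.cells
            if _var("SCR", c) not in self.network.clamps
        ]


def build_meta_grn(variant: str = "B_prime", mobility: MobilitySpec | None = None) -> MetaGRN:
    """Construct the coupled meta-GRN (model B' only).

    Composite rules per cell X (ANY_* = OR over all four cells):

    * ``SHR@V`` clamped 1; ``SHR@X`` = OR over neighbours Y of
      ``SHR@Y AND NOT SCR@Y``;
    * ``Auxin@V``, ``Auxin@C`` clamped 1; ``Auxin@Q = Auxin@V OR
      Auxin@C``; ``Auxin@E = Auxin@Q``;
    * ``Aux/IAA@X = NOT (Auxin@X OR WOX5@X)`` — the WOX5 arm of the
      activator-inhibitor motif; ``ARF@X = NOT Aux/IAA@X``;
      ``PLT@X = ARF@X``;
    * ``SCR@V`` clamped 0; elsewhere the single-cell B' rule;
    * ``WOX5@Q = ARF@Q AND SHR@Q AND SCR@Q`` (local activation inside
      the QC); elsewhere ``... AND NOT ANY_CLEX`` (long-range
      inhibition);
    * ``CLEX@Q = 0``; elsewhere ``SHR@X AND (MGP@X OR CLEX@X OR
      ANY_WOX5)`` (non-cell-autonomous activation by WOX5 outside the
      QC).
    """
    if variant != "B_prime":
        raise NetworkError(
            f"the coupled meta-GRN is defined for variant 'B_prime' only, got {variant!r}"
        )
    mob = mobility if mobility is not None else MobilitySpec()

    any_wox5 = "(" + " OR ".join(_var("WOX5", c) for c in CELLS) + ")"
    any_clex = "(" + " OR ".join(_var("CLEX", c) for c in CELLS) + ")"

    nodes: list[str] = [_var(n, c) for c in CELLS for n in NODES_B]
    rules: list[RuleTable] = []
    clamps: dict[str, int] = {
        _var("SHR", "V"): 1,
        _var("SCR", "V"): 0,
        _var("Auxin", "V"): 1,
        _var("Auxin", "C"): 1,
    }

    def rule(node: str, cell: str, expression: str) -> None:
        rules.append(RuleTable.from_expression(_var(node, cell), expression))

    for X in CELLS:
        rule("PLT", X, _var("ARF", X))
        rule("ARF", X, f"NOT {_var('Aux/IAA', X)}")
        rule("Aux/IAA", X, f"NOT ({_var('Auxin', X)} OR {_var('WOX5', X)})")
        rule("JKD", X, f"{_var('SHR', X)} AND {_var('SCR', X)}")
        rule("MGP", X, f"{_var('SHR', X)} AND {_var('SCR', X)} AND NOT {_var('WOX5', X)}")

        # auxin: clamped source in V and C, acropetal flow into Q then E
        if X == "V":
            rule("Auxin", X, "1")
        elif X == "C":
            rule("Auxin", X, "1")
        elif X == "Q":
            rule("Auxin", X, f"{_var('Auxin', 'V')} OR {_var('Auxin', 'C')}")
        else:
            rule("Auxin", X, _var("Auxin", "Q"))

        # SHR: produced in V only, moves from neighbours lacking SCR
        if X == "V":
            rule("SHR", X, "1")
        else:
            terms = [
                f"({_var('SHR', Y)} AND NOT {_var('SCR', Y)})" for Y in mob.neighbours(X)
            ]
            rule("SHR", X, " OR ".join(terms) if terms else "0")

        # SCR: transcription impossible in V; single-cell B' rule elsewhere
        if X == "V":
            rule("SCR", X, "0")
        else:
            rule("SCR", X, f"{_var('SHR', X)} AND {_var('SCR', X)}")

        # WOX5: local activator in the QC, long-range CLEX inhibition outside
        base = f"{_var('ARF', X)} AND {_var('SHR', X)} AND {_var('SCR', X)}"
        if X == "Q":
            rule("WOX5", X, base)
        else:
            rule("WOX5", X, f"{base} AND NOT {any_clex}")

        # CLEX: silent in the QC, activated non-cell-autonomously by WOX5
        if X == "Q":
            rule("CLEX", X, "0")
        else:
            rule("CLEX", X, f"{_var('SHR', X)} AND ({_var('MGP', X)} OR {_var('CLEX', X)} OR {any_wox5})")

    network = build_network(nodes, rules, clamps)
    return MetaGRN(network=network, mobility=mob)


@dataclass
class SpatialPattern:
    """Per-cell projection of a global state, with cell-type labels."""

    cells: dict[str, dict[str, int]]
    labels: dict[str, str | None]

    def matches_wild_type(self) -> bool:
        return all(self.labels.get(c) == EXPECTED_FATE[c] for c in CELLS)


def _label_cell(profile: tuple[int, ...]) -> str | None:
    """Exact-match label of a 10-node projection against the B' profiles."""
    ref = reference_profiles("B_prime")
    for cell, states in ref.expected_states().items():
        if profile in states:
            return cell
    return None


def pattern_of(meta: MetaGRN, state: tuple[int, ...]) -> SpatialPattern:
    cells = {}
    labels = {}
    for c in CELLS:
        proj = meta.project(state, c)
        cells[c] = dict(zip(meta.cell_nodes, proj))
        labels[c] = _label_cell(proj)
    return SpatialPattern(cells=cells, labels=labels)


def _scr_mask(meta: MetaGRN) -> int:
    n = meta.network.n
    mask = 0
    for name in meta.scr_free_vars:
        mask |= 1 << (n - 1 - meta.network.node_index[name])
    return mask


def _prepare_initial(meta: MetaGRN, value: int, scr_convention: bool) -> int:
    s = meta.network.apply_clamps(int(value))
    if scr_convention:
        s |= _scr_mask(meta)
    return s


def run_spatial(
    meta: MetaGRN,
    initial,
    scr_convention: bool = True,
) -> tuple[Trajectory, SpatialPattern]:
    """Iterate one initial condition of the meta-GRN to its attractor.

    Under the SCR convention, all non-clamped SCR variables are forced
    to 1 at t=0 and t=1 and released afterwards.  Returns the trajectory
    (recorded from t=0) and the spatial pattern of the attractor state
    (first state of the cycle).
    """
    net = meta.network
    s0 = initial if isinstance(initial, (int, np.integer)) else net.encode(initial)
    s0 = _prepare_initial(meta, int(s0), scr_convention)
    prefix: list[int] = []
    if scr_convention:
        s1 = step_int(net, s0) | _scr_mask(meta)
        s1 = net.apply_clamps(s1)
        prefix = [s0]
        start = s1
    else:
        start = s0
    tail = _trajectory(net, start)
    states = tuple(net.decode(p) for p in prefix) + tail.states
    traj = Trajectory(
        states=states,
        transient_length=tail.transient_length + len(prefix),
        attractor=tail.attractor,
    )
    return traj, pattern_of(meta, tail.attractor.states[0])


def find_global_attractors(
    meta: MetaGRN,
    n_samples: int = 100_000,
    seed: int = 0,
    scr_convention: bool = True,
    max_steps: int = 1000,
) -> AttractorSet:
    """Distinct attractors over seeded random initial configurations.

    The full 2**40 space is beyond explicit enumeration, so uniqueness
    is probed by a seeded uniform sample of initial states, advanced in
    lockstep (vectorised) until each reaches a fixed point; the rare
    trajectory that has not settled within ``max_steps`` is finished
    with per-state cycle detection, so cyclic attractors would also be
    reported.
    """
    if n_samples < 1:
        raise NetworkError("n_samples must be >= 1")
    net = meta.network
    rng = np.random.default_rng(seed)
    states = rng.integers(0, net.space_size, size=n_samples, dtype=np.uint64)
    mask = np.uint64(_scr_mask(meta)) if scr_convention else np.uint64(0)
    states = (states & ~net._clamp_mask) | net._clamp_bits
    states |= mask
    states = batch_step(net, states) | mask  # t=1, SCR still forced
    active = np.ones(len(states), dtype=bool)
    for _ in range(max_steps):
        if not active.any():
            break
        nxt = batch_step(net, states[active])
        settled = nxt == states[active]
        idx = np.flatnonzero(active)
        states[idx] = nxt
        active[idx[settled]] = False

    counts: dict[tuple[int, ...], int] = {}
    fixed_states, fixed_counts = np.unique(states[~active], return_counts=True)
    for s, c in zip(fixed_states.tolist(), fixed_counts.tolist()):
        counts[(int(s),)] = counts.get((int(s),), 0) + int(c)
    # unsettled leftovers: resolve cycles individually
    for s in states[active].tolist():
        tr = _trajectory(net, int(s))
        key = tuple(int(net.encode(x)) for x in tr.attractor.states)
        counts[key] = counts.get(key, 0) + 1

    keys = sorted(counts)
    attractors = [
        Attractor(tuple(net.decode(v) for v in key), period=len(key)) for key in keys
    ]
    return AttractorSet(
        attractors=attractors,
        basin_counts=[counts[k] for k in keys],
        space_size=n_samples,
        mode="sampled",
        seed=seed,
    )


def spatial_mutant_model(meta: MetaGRN, node: str, kind: str) -> MetaGRN:
    """The meta-GRN with one intracellular gene clamped in all four cells."""
    if node not in meta.cell_nodes:
        raise NetworkError(f"unknown intracellular node {node!r}")
    if kind not in ("loss", "gain"):
        raise NetworkError(f"kind must be 'loss' or 'gain', got {kind!r}")
    value = 0 if kind == "loss" else 1
    net = meta.network
    clamps = dict(net.clamps)
    for c in CELLS:
        clamps[_var(node, c)] = value
    return MetaGRN(
        network=build_network(net.nodes, net.rules, clamps),
        mobility=meta.mobility,
        cells=meta.cells,
        cell_nodes=meta.cell_nodes,
    )


def simulate_spatial_mutant(
    meta: MetaGRN,
    node: str,
    kind: str,
    n_samples: int = 20_000,
    seed: int = 0,
    scr_convention: bool | str = "both",
) -> AttractorSet:
    """Clamp one intracellular gene in all four cells and re-sample.

    ``kind`` is ``loss`` (clamp 0) or ``gain`` (clamp 1).  With
    ``scr_convention="both"`` (default) the run is repeated under both
    SCR-initialisation conventions and the attractor sets merged: some
    mutant outcomes (e.g. the CEpI-plus-SHR state of the SHR gain) are
    reachable only when SCR may start off.  Pass True/False to probe a
    single convention — comparisons against the wild type must use the
    same convention on both sides, since without the convention SCR
    never bootstraps and many frozen SCR-off states coexist.  Clamps
    override the convention (an scr loss keeps SCR at 0 throughout).
    """
    mutant = spatial_mutant_model(meta, node, kind)
    conventions = (True, False) if scr_convention == "both" else (bool(scr_convention),)
    merged: dict[tuple, int] = {}
    for i, convention in enumerate(conventions):
        aset = find_global_attractors(
            mutant, n_samples=n_samples, seed=seed + i, scr_convention=convention
        )
        for a, c in zip(aset.attractors, aset.basin_counts):
            merged[a.key()] = merged.get(a.key(), 0) + c
    keys = sorted(merged)
    attractors = [Attractor(k, period=len(k)) for k in keys]
    return AttractorSet(
        attractors=attractors,
        basin_counts=[merged[k] for k in keys],
        space_size=len(conventions) * n_samples,
        mode="sampled",
        seed=seed,
    )


def continuous_spatial_attractors(
    meta: MetaGRN,
    n_starts: int = 100,
    seed: int = 0,
    h: float = 50.0,
    t_end: float = 150.0,
) -> tuple[ContinuousModel, list[tuple[int, ...]]]:
    """Terminal rounded states of the continuous meta-GRN.

    Integrates the logistic-ODE version from seeded random interior
    points with all free SCR levels started at 1 (the continuous form of
    the initialisation convention; clamped variables stay at their
    clamp).  Returns the continuous model and the rounded terminal state
    of each run.
    """
    cmodel = to_continuous(meta.network, h=h)
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(0.0, 1.0, size=(n_starts, meta.network.n))
    for name in meta.scr_free_vars:
        x0[:, meta.network.node_index[name]] = 1.0
    xf = integrate_batch(cmodel, x0, t_end=t_end)
    return cmodel, [tuple(int(round(v)) for v in row) for row in xf]
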