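"""The four single-cell root stem-cell-niche (SCN) models.

The root SCN network couples the auxin readout pathway (auxin -> Aux/IAA
-> ARF -> PLT) to the SHR/SCR radial module (SHR, SCR, JKD, MGP) through
WOX5, the quiescent-centre identity gene.  Four variants are analysed:

* **A / A'** — WOX5 and MGP repress each other (mutual exclusion of the
  QC and CEI fates).
* **B / B'** — WOX5 is instead repressed by the hypothetical CLE-like
  gene CLEX, which adds a tenth node.
* The primed variants differ from their base model in a single output
  bit of the SCR truth table (line 14, input pattern SHR=1, SCR=1,
  JKD=0, MGP=1), which makes SCR transcription independent of JKD.

Each variant's attractors are fixed points matching the expression
profiles of the four SCN cell types: quiescent centre (QC), vascular
initials, cortex/endodermis initials (CEI) and columella/epidermis
initials (CEpI); model-B variants recover the vascular profile twice,
with CLEX in either state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import (
    Attractor,
    AttractorSet,
    NetworkError,
    NetworkModel,
    RuleTable,
    build_network,
    find_attractors,
)

__all__ = [
    "VARIANTS",
    "CELL_TYPES",
    "NODES_A",
    "NODES_B",
    "ReferenceProfiles",
    "ValidationReport",
    "build_scn_model",
    "reference_profiles",
    "validate_against_reference",
    "extend_with_markers",
    "label_attractors",
    "nodes_for_variant",
]

VARIANTS = ("A", "A_prime", "B", "B_prime")
CELL_TYPES = ("QC", "vascular", "CEI", "CEpI")

#: canonical single-cell node order; CLEX is appended for model-B variants
NODES_A = ("PLT", "Auxin", "ARF", "Aux/IAA", "SHR", "SCR", "JKD", "MGP", "WOX5")
NODES_B = NODES_A + ("CLEX",)

#: declared SCR inputs — fixes arity 4 in every variant so that A and A'
#: (and B and B') differ in exactly one truth-table output bit
_SCR_INPUTS = ("SHR", "SCR", "JKD", "MGP")


def load_packaged_rules(variant: str) -> NetworkModel:
    """Read a variant's shipped rule file (equivalent to build_scn_model)."""
    _check_variant(variant)
    from importlib import resources

    from .io import parse_rules

    text = resources.files("rootscn.data").joinpath(f"rules_{variant}.txt").read_text()
    return parse_rules(text)


def nodes_for_variant(variant: str) -> tuple[str, ...]:
    _check_variant(variant)
    return NODES_A if variant in ("A", "A_prime") else NODES_B


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise NetworkError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def build_scn_model(variant: str) -> NetworkModel:
    """Reference rule set of one SCN model variant.

    The auxin pathway is a linear input chain (auxin is a constant
    source, Aux/IAA is degraded by auxin, ARF is released by Aux/IAA
    loss, PLT reads ARF).  SHR has no regulators, so it copies its own
    initial state.  SCR requires SHR and itself, with JKD enhancing and
    MGP repressing it in the unprimed variants.  WOX5 carries a
    self-maintenance disjunct in its antagonism with MGP (A/A') or CLEX
    (B/B'), which removes the two-cycle a symmetric mutual repression
    would produce under synchronous updating.
    """
    _check_variant(variant)
    primed = variant.endswith("_prime")
    b_family = variant.startswith("B")

    scr_expr = "SHR AND SCR" if primed else "SHR AND SCR AND (JKD OR NOT MGP)"
    wox5_antagonist = "CLEX" if b_family else "MGP"

    rules = [
        RuleTable.from_expression("PLT", "ARF"),
        RuleTable.from_expression("Auxin", "1"),
        RuleTable.from_expression("ARF", "NOT Aux/IAA"),
        RuleTable.from_expression("Aux/IAA", "NOT Auxin"),
        RuleTable.from_expression("SHR", "SHR"),
        RuleTable.from_expression("SCR", scr_expr, inputs=_SCR_INPUTS),
        RuleTable.from_expression("JKD", "SHR AND SCR"),
        RuleTable.from_expression("MGP", "SHR AND SCR AND NOT WOX5"),
        RuleTable.from_expression(
            "WOX5", f"ARF AND SHR AND SCR AND (NOT {wox5_antagonist} OR WOX5)"
        ),
    ]
    nodes = NODES_A
    if b_family:
        nodes = NODES_B
        rules.append(
            RuleTable.from_expression("CLEX", "SHR AND NOT WOX5 AND (MGP OR CLEX)")
        )
    return build_network(nodes, rules)


@dataclass(frozen=True)
class ReferenceProfiles:
    """Expected cell-type expression profiles for one model family.

    ``free_nodes`` marks nodes whose value is unconstrained in a given
    cell type; such a profile must be matched by attractors carrying
    *both* values of each free node (the duplicated vascular attractor
    of the model-B variants).
    """

    nodes: tuple[str, ...]
    profiles: dict[str, tuple[int, ...]]
    free_nodes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def expected_states(self) -> dict[str, list[tuple[int, ...]]]:
        """Per cell type, the list of concrete states that realise it."""
        out: dict[str, list[tuple[int, ...]]] = {}
        for cell, profile in self.profiles.items():
            states = [profile]
            for free in self.free_nodes.get(cell, ()):
                idx = self.nodes.index(free)
                states = [
                    tuple(v if i != idx else b for i, v in enumerate(s))
                    for s in states
                    for b in (0, 1)
                ]
            out[cell] = states
        return out


def reference_profiles(variant: str) -> ReferenceProfiles:
    """Observed/simulated cell-type configurations for a variant family."""
    _check_variant(variant)
    a_profiles = {
        #       PLT Aux ARF IAA SHR SCR JKD MGP WOX5
        "QC": (1, 1, 1, 0, 1, 1, 1, 0, 1),
        "vascular": (1, 1, 1, 0, 1, 0, 0, 0, 0),
        "CEI": (1, 1, 1, 0, 1, 1, 1, 1, 0),
        "CEpI": (1, 1, 1, 0, 0, 0, 0, 0, 0),
    }
    if variant in ("A", "A_prime"):
        return ReferenceProfiles(NODES_A, a_profiles)
    b_profiles = {
        "QC": a_profiles["QC"] + (0,),
        "vascular": a_profiles["vascular"] + (1,),  # CLEX may be 0 or 1
        "CEI": a_profiles["CEI"] + (1,),
        "CEpI": a_profiles["CEpI"] + (0,),
    }
    return ReferenceProfiles(NODES_B, b_profiles, free_nodes={"vascular": ("CLEX",)})


@dataclass
class ValidationReport:
    """Outcome of comparing a model's attractors with reference profiles."""

    passed: bool
    matched: dict[str, list[tuple[int, ...]]]
    missing: list[str]
    spurious: list[tuple[int, ...]]
    non_fixed_points: int
    notes: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_against_reference(
    model: NetworkModel, profiles: ReferenceProfiles
) -> ValidationReport:
    """Exhaustive attractor search compared against reference profiles.

    The comparison projects attractor states onto the profile's node set
    (so marker-extended models validate too).  It passes iff every
    expected state is realised by exactly one attractor, no unexpected
    projected state appears, and all attractors are fixed points.  A
    profile with free nodes must be matched in *all* of its concrete
    states (e.g. vascular with CLEX on and off).
    """
    missing_nodes = [n for n in profiles.nodes if n not in model.node_index]
    if missing_nodes:
        raise NetworkError(f"model lacks profile nodes: {missing_nodes}")
    idx = [model.node_index[n] for n in profiles.nodes]

    aset = find_attractors(model, mode="exhaustive")
    non_fixed = sum(1 for a in aset.attractors if not a.is_fixed_point)
    projected: list[tuple[int, ...]] = [
        tuple(a.states[0][i] for i in idx) for a in aset.attractors if a.is_fixed_point
    ]

    expected = profiles.expected_states()
    matched: dict[str, list[tuple[int, ...]]] = {}
    missing: list[str] = []
    remaining = list(projected)
    notes: list[str] = []
    for cell, states in expected.items():
        got = [s for s in states if s in remaining]
        for s in got:
            remaining.remove(s)
        matched[cell] = got
        if len(got) < len(states):
            missing.append(cell)
    spurious = remaining
    if non_fixed:
        notes.append(f"{non_fixed} cyclic attractor(s) found")
    if len(projected) != len(set(projected)):
        notes.append("multiple attractors project onto the same profile state")
    passed = not missing and not spurious and not non_fixed and not notes
    return ValidationReport(passed, matched, missing, spurious, non_fixed, notes)


def extend_with_markers(model: NetworkModel) -> NetworkModel:
    """Append the PINX and QC46 marker genes as pure outputs.

    PINX (a generic PIN auxin-efflux gene) follows PLT; QC46, a QC
    marker, requires PLT together with the QC-defining combination SHR,
    SCR and WOX5.  Neither feeds back, so the projection of every
    attractor onto the original nodes is unchanged.
    """
    for marker in ("PINX", "QC46"):
        if marker in model.node_index:
            raise NetworkError(f"marker node {marker!r} already present")
    rules = list(model.rules) + [
        RuleTable.from_expression("PINX", "PLT"),
        RuleTable.from_expression("QC46", "PLT AND SHR AND SCR AND WOX5"),
    ]
    return build_network(model.nodes + ("PINX", "QC46"), rules, model.clamps)


def label_attractors(
    aset: AttractorSet,
    profiles: ReferenceProfiles,
    model: NetworkModel,
    ignore: tuple[str, ...] = (),
) -> AttractorSet:
    """Attach cell-type labels to fixed-point attractors.

    Exact matches (on the profile nodes, minus ``ignore``) get the plain
    cell-type name; otherwise the nearest profile by Hamming distance is
    used with a ``-like`` suffix.  Cyclic attractors are labelled
    ``cycle(p)``.
    """
    keep = [
        (model.node_index[n], profiles.nodes.index(n))
        for n in profiles.nodes
        if n not in ignore and n in model.node_index
    ]
    expected = profiles.expected_states()
    labelled: list[Attractor] = []
    for a in aset.attractors:
        if not a.is_fixed_point:
            labelled.append(a.with_label(f"cycle({a.period})"))
            continue
        state = a.states[0]
        best, best_d = None, None
        exact = None
        for cell, states in expected.items():
            for s in states:
                d = sum(state[mi] != s[pi] for mi, pi in keep)
                if d == 0:
                    exact = cell
                if best_d is None or d < best_d:
                    best, best_d = cell, d
        labelled.append(a.with_label(exact if exact is not None else f"{best}-like"))
    return AttractorSet(
        labelled,
        aset.basin_counts,
        aset.space_size,
        aset.mode,
        aset.seed,
        aset.assignments,
    )
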