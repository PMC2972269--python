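"""Reading and writing logical-rule files.

Two plain-text dialects are supported and round-trip losslessly:

* expression files — one ``TARGET = <expr>`` line per node, with the
  operators AND, OR, NOT, parentheses and the constants 0/1.  A line may
  declare an explicit input order in brackets after the target, e.g.
  ``SCR[SHR,SCR,JKD,MGP] = SHR AND SCR``, which fixes the truth-table
  arity even for inputs the expression does not mention.  Clamps are
  written as ``!name = value`` lines.

* truth-table files — TSV with the header ``target  inputs  outputs``;
  ``inputs`` is a comma-separated list and ``outputs`` a 2**k bit string
  in row order all-zeros .. all-ones (inputs most-significant-first).

A best-effort SBML-qual export is provided for interoperability with
logical-modelling tools.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

from . import expr as ex
from .network import NetworkError, NetworkModel, RuleTable, build_network

__all__ = [
    "read_rules",
    "write_rules",
    "parse_rules",
    "format_rules",
    "to_sbml_qual",
]


def parse_rules(text: str) -> NetworkModel:
    """Parse rule text in either dialect (auto-detected)."""
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise NetworkError("empty rule file")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    if header[:3] == ["target", "inputs", "outputs"]:
        return _parse_table_dialect(lines[1:])
    return _parse_expr_dialect(lines)


def _parse_expr_dialect(lines: list[str]) -> NetworkModel:
    rules: list[RuleTable] = []
    clamps: dict[str, int] = {}
    order: list[str] = []
    for ln in lines:
        if "=" not in ln:
            raise NetworkError(f"malformed rule line: {ln!r}")
        lhs, rhs = ln.split("=", 1)
        lhs = lhs.strip()
        rhs = rhs.strip()
        if lhs.startswith("!"):
            clamps[lhs[1:].strip()] = int(rhs)
            continue
        inputs = None
        if lhs.endswith("]") and "[" in lhs:
            lhs, decl = lhs[:-1].split("[", 1)
            lhs = lhs.strip()
            inputs = tuple(s.strip() for s in decl.split(",") if s.strip())
        rules.append(RuleTable.from_expression(lhs, rhs, inputs=inputs))
        order.append(lhs)
    return build_network(order, rules, clamps)


def _parse_table_dialect(lines: list[str]) -> NetworkModel:
    rules: list[RuleTable] = []
    clamps: dict[str, int] = {}
    order: list[str] = []
    for ln in lines:
        cols = [c.strip() for c in ln.split("\t")]
        if len(cols) < 3:
            raise NetworkError(f"malformed table line: {ln!r}")
        target, inputs_s, outputs_s = cols[0], cols[1], cols[2]
        if target.startswith("!"):
            clamps[target[1:]] = int(outputs_s)
            continue
        inputs = tuple(s.strip() for s in inputs_s.split(",") if s.strip())
        outputs = [int(c) for c in outputs_s]
        rules.append(RuleTable(target, inputs, outputs))
        order.append(target)
    return build_network(order, rules, clamps)


def format_rules(model: NetworkModel, dialect: str = "expr") -> str:
    """Serialise a model to rule text (``expr`` or ``table`` dialect)."""
    out = _io.StringIO()
    if dialect == "expr":
        for rule in model.rules:
            node = rule.as_expression()
            used = ex.variables(node)
            lhs = rule.target
            if rule.inputs != used:
                lhs += "[" + ",".join(rule.inputs) + "]"
            out.write(f"{lhs} = {ex.to_string(node)}\n")
        for name, value in model.clamps.items():
            out.write(f"!{name} = {value}\n")
    elif dialect == "table":
        out.write("target\tinputs\toutputs\n")
        for rule in model.rules:
            bits = "".join(map(str, rule.outputs))
            out.write(f"{rule.target}\t{','.join(rule.inputs)}\t{bits}\n")
        for name, value in model.clamps.items():
            out.write(f"!{name}\t\t{value}\n")
    else:
        raise NetworkError(f"unknown dialect {dialect!r}")
    return out.getvalue()


def read_rules(path: str | Path) -> NetworkModel:
    return parse_rules(Path(path).read_text())


def write_rules(model: NetworkModel, path: str | Path, dialect: str = "expr") -> None:
    Path(path).write_text(format_rules(model, dialect))


# -- SBML-qual export (best effort) ----------------------------------------------

_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
_MATH_NS = "http://www.w3.org/1998/Math/MathML"


def _sanitize(name: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in name)
    return out if out and not out[0].isdigit() else "n_" + out


def _mathml(node: ex.Expr, parent, E) -> None:
    M = "{%s}" % _MATH_NS
    if isinstance(node, ex.Var):
        apply = E(M + "apply")
        apply.append(E(M + "eq"))
        ci = E(M + "ci")
        ci.text = " %s " % _sanitize(node.name)
        apply.append(ci)
        cn = E(M + "cn")
        cn.set("type", "integer")
        cn.text = "1"
        apply.append(cn)
        parent.append(apply)
    elif isinstance(node, ex.Const):
        cn = E(M + "cn")
        cn.set("type", "integer")
        cn.text = str(node.value)
        parent.append(cn)
    else:
        apply = E(M + "apply")
        opname = {ex.Not: "not", ex.And: "and", ex.Or: "or"}[type(node)]
        apply.append(E(M + opname))
        args = (node.arg,) if isinstance(node, ex.Not) else node.args
        for a in args:
            _mathml(a, apply, E)
        parent.append(apply)


def to_sbml_qual(model: NetworkModel, model_id: str = "network") -> bytes:
    """Serialise a model as an SBML level-3 qual document."""
    from lxml import etree

    E = etree.Element
    S = "{%s}" % _SBML_NS
    Q = "{%s}" % _QUAL_NS
    nsmap = {None: _SBML_NS, "qual": _QUAL_NS}
    sbml = E(S + "sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    sbml.set(Q + "required", "true")
    mdl = E(S + "model")
    mdl.set("id", _sanitize(model_id))
    sbml.append(mdl)
    species_list = E(Q + "listOfQualitativeSpecies")
    mdl.append(species_list)
    for name in model.nodes:
        sp = E(Q + "qualitativeSpecies")
        sp.set(Q + "id", _sanitize(name))
        sp.set(Q + "name", name)
        sp.set(Q + "maxLevel", "1")
        sp.set(Q + "constant", "false")
        if name in model.clamps:
            sp.set(Q + "initialLevel", str(model.clamps[name]))
        species_list.append(sp)
    transitions = E(Q + "listOfTransitions")
    mdl.append(transitions)
    for rule in model.rules:
        tr = E(Q + "transition")
        tr.set(Q + "id", "tr_" + _sanitize(rule.target))
        if rule.inputs:
            inputs = E(Q + "listOfInputs")
            for i, inp in enumerate(dict.fromkeys(rule.inputs)):
                el = E(Q + "input")
                el.set(Q + "id", f"tr_{_sanitize(rule.target)}_in_{i}")
                el.set(Q + "qualitativeSpecies", _sanitize(inp))
                el.set(Q + "transitionEffect", "none")
                inputs.append(el)
            tr.append(inputs)
        outputs = E(Q + "listOfOutputs")
        out = E(Q + "output")
        out.set(Q + "qualitativeSpecies", _sanitize(rule.target))
        out.set(Q + "transitionEffect", "assignmentLevel")
        outputs.append(out)
        tr.append(outputs)
        terms = E(Q + "listOfFunctionTerms")
        default = E(Q + "defaultTerm")
        default.set(Q + "resultLevel", "0")
        terms.append(default)
        term = E(Q + "functionTerm")
        term.set(Q + "resultLevel", "1")
        math = E("{%s}math" % _MATH_NS)
        _mathml(rule.as_expression(), math, E)
        term.append(math)
        terms.append(term)
        tr.append(terms)
        transitions.append(tr)
    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True)
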