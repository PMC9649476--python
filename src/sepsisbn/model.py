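"""Boolean network container and the shipped TLR4 early-sepsis model.

A :class:`BooleanModel` bundles an ordered node list, one parsed update rule
per node, the threshold-tag delay map, a five-way node classification
(pathogen / host_cell / mediator / outcome / other), the initial state, the
clinical-surrogate endpoint nodes (with their beneficial direction of
change), and the default perturbation screen set.

The shipped model — 42 nodes covering the TLR4 cascade, innate and adaptive
immune cells, complement and coagulation — is loaded with :func:`load_tlr4`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .rules import (
    RuleExpr,
    Thr,
    flatten_delays,
    parse_rule,
    referenced_nodes,
    referenced_tags,
    serialize,
)

__all__ = [
    "BooleanModel",
    "ModelValidationError",
    "load_model",
    "load_tlr4",
    "read_rules_file",
    "network_stats",
    "export_bnet",
    "import_bnet",
    "NODE_CLASSES",
]

NODE_CLASSES = ("pathogen", "host_cell", "mediator", "outcome", "other")

#: class counts of the shipped TLR4 model, checked at load time
_TLR4_CLASS_COUNTS = {"pathogen": 3, "host_cell": 13, "mediator": 19,
                      "outcome": 4, "other": 3}


class ModelValidationError(ValueError):
    """A model failed referential or metadata validation."""


@dataclass
class BooleanModel:
    """A delay-aware Boolean network with analysis metadata.

    ``endpoints`` maps endpoint node -> beneficial direction
    (``"increase"`` or ``"decrease"``).
    """

    nodes: list[str]
    rules: dict[str, RuleExpr]
    delays: dict[str, int] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)
    initial_state: dict[str, int] = field(default_factory=dict)
    endpoints: dict[str, str] = field(default_factory=dict)
    screen_set: list[str] = field(default_factory=list)
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------

    def validate(self) -> None:
        seen: set[str] = set()
        for n in self.nodes:
            if n in seen:
                raise ModelValidationError(f"duplicate node {n!r}")
            seen.add(n)
        missing = [n for n in self.nodes if n not in self.rules]
        if missing:
            raise ModelValidationError(f"nodes without a rule: {missing}")
        extra = [n for n in self.rules if n not in seen]
        if extra:
            raise ModelValidationError(f"rules for undeclared nodes: {extra}")
        for target, expr in self.rules.items():
            for ref in referenced_nodes(expr):
                if ref not in seen:
                    raise ModelValidationError(
                        f"rule for {target!r} references undeclared node {ref!r}")
            for tag in referenced_tags(expr):
                if tag not in self.delays:
                    raise ModelValidationError(
                        f"rule for {target!r} uses threshold tag {tag!r} "
                        f"with no delay in the metadata")
        for tag, d in self.delays.items():
            if not (isinstance(d, int) and d >= 1):
                raise ModelValidationError(
                    f"delay for tag {tag!r} must be a positive integer, got {d!r}")
        for n, cls in self.classes.items():
            if n not in seen:
                raise ModelValidationError(f"classified unknown node {n!r}")
            if cls not in NODE_CLASSES:
                raise ModelValidationError(f"unknown class {cls!r} for {n!r}")
        for n in self.initial_state:
            if n not in seen:
                raise ModelValidationError(f"initial state for unknown node {n!r}")
        for n, direction in self.endpoints.items():
            if n not in seen:
                raise ModelValidationError(f"endpoint {n!r} is not a node")
            if direction not in ("increase", "decrease"):
                raise ModelValidationError(
                    f"endpoint {n!r}: beneficial direction must be "
                    f"'increase' or 'decrease', got {direction!r}")
        for n in self.screen_set:
            if n not in seen:
                raise ModelValidationError(f"screen-set node {n!r} is not a node")

    # -- convenience ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def endpoint_nodes(self) -> list[str]:
        return list(self.endpoints)

    def nodes_of_class(self, cls: str) -> list[str]:
        if cls not in NODE_CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        return [n for n in self.nodes if self.classes.get(n) == cls]

    def initial_vector(self):
        import numpy as np

        v = np.zeros(self.n_nodes, dtype=np.int8)
        for n, bit in self.initial_state.items():
            v[self.node_index[n]] = 1 if bit else 0
        return v

    def has_delays(self) -> bool:
        return any(isinstance(e, Thr) or referenced_tags(e)
                   for e in self.rules.values())

    @classmethod
    def from_rules(cls, text: str, *, delays: Mapping[str, int] | None = None,
                   initial_state: Mapping[str, int] | None = None,
                   name: str = "model", **kwargs) -> "BooleanModel":
        """Build a model from rules text alone (used by toy fixtures)."""
        nodes, rules = read_rules_text(text)
        return cls(nodes=nodes, rules=rules, delays=dict(delays or {}),
                   initial_state=dict(initial_state or {}), name=name, **kwargs)


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def read_rules_text(text: str) -> tuple[list[str], dict[str, RuleExpr]]:
    """Parse a rules document: one ``Node = expr`` per line, '#' comments."""
    nodes: list[str] = []
    rules: dict[str, RuleExpr] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        target, expr = parse_rule(line, line=lineno)
        if target in rules:
            raise ModelValidationError(
                f"duplicate rule for node {target!r} (line {lineno})")
        nodes.append(target)
        rules[target] = expr
    return nodes, rules


def read_rules_file(path: str | Path) -> tuple[list[str], dict[str, RuleExpr]]:
    return read_rules_text(Path(path).read_text())


def _load_metadata(path: str | Path) -> dict:
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict):
        raise ModelValidationError(f"metadata file {path} is not a mapping")
    return meta


def load_model(rules_path: str | Path, metadata_path: str | Path,
               name: str | None = None) -> BooleanModel:
    """Load and validate a model from a rules file plus a metadata sidecar.

    The sidecar is YAML (or JSON, a YAML subset) with keys ``delays``,
    ``classes``, ``initial_state``, ``endpoints`` and ``screen_set``.
    Validation failures raise :class:`ModelValidationError` naming the
    offending node or reference.
    """
    nodes, rules = read_rules_file(rules_path)
    meta = _load_metadata(metadata_path)
    classes: dict[str, str] = {}
    for cls, members in (meta.get("classes") or {}).items():
        for n in members or []:
            if n in classes:
                raise ModelValidationError(f"node {n!r} classified twice")
            classes[n] = cls
    endpoints_raw = meta.get("endpoints") or {}
    if isinstance(endpoints_raw, list):  # direction-less form
        endpoints = {n: "increase" for n in endpoints_raw}
    else:
        endpoints = dict(endpoints_raw)
    model = BooleanModel(
        nodes=nodes,
        rules=rules,
        delays=dict(meta.get("delays") or {}),
        classes=classes,
        initial_state=dict(meta.get("initial_state") or {}),
        endpoints=endpoints,
        screen_set=list(meta.get("screen_set") or []),
        name=name or Path(rules_path).stem,
    )
    return model


def load_tlr4() -> BooleanModel:
    """Load the shipped 42-node TLR4 early-sepsis model.

    Checks the published structure: 42 nodes, class counts
    3 pathogen / 13 host-cell / 19 mediator / 4 outcome / 3 other, and the
    4 endpoint nodes (Phagocytosis, MAC, Thrombosis, Ang2).
    """
    data = resources.files("sepsisbn.data")
    with resources.as_file(data / "tlr4_rules.txt") as rp, \
            resources.as_file(data / "tlr4_meta.yaml") as mp:
        model = load_model(rp, mp, name="tlr4_sepsis")
    if model.n_nodes != 42:
        raise ModelValidationError(
            f"shipped model has {model.n_nodes} nodes, expected 42")
    counts = {c: len(model.nodes_of_class(c)) for c in NODE_CLASSES}
    if counts != _TLR4_CLASS_COUNTS:
        raise ModelValidationError(
            f"shipped class counts {counts} != {_TLR4_CLASS_COUNTS}")
    if set(model.endpoints) != {"Phagocytosis", "MAC", "Thrombosis", "Ang2"}:
        raise ModelValidationError("shipped endpoint set is wrong")
    active = [n for n, b in model.initial_state.items() if b]
    if active != ["Infection"]:
        raise ModelValidationError("shipped initial state must be Infection only")
    return model


# ---------------------------------------------------------------------------
# Structure summary / export
# ---------------------------------------------------------------------------

def edges(model: BooleanModel) -> list[tuple[str, str]]:
    """Distinct (regulator -> target) pairs extracted from the rule ASTs.

    VAR and THR references both count; a regulator appearing several times in
    one rule counts once.
    """
    out: list[tuple[str, str]] = []
    for target in model.nodes:
        for reg in sorted(referenced_nodes(model.rules[target])):
            out.append((reg, target))
    return out


def network_stats(model: BooleanModel) -> dict:
    """Node count, per-class counts and AST-derived edge count."""
    return {
        "node_count": model.n_nodes,
        "class_counts": {c: len(model.nodes_of_class(c)) for c in NODE_CLASSES},
        "edge_count": len(edges(model)),
        "endpoint_count": len(model.endpoints),
        "delay_tags": dict(model.delays),
    }


def export_edge_list(model: BooleanModel, path: str | Path) -> None:
    """Dump the regulator->target edges as a TSV for external visualization."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["regulator", "target"])
        w.writerows(edges(model))


def _bnet_name(name: str) -> str:
    return name.replace("-", "_")


def export_bnet(model: BooleanModel, path: str | Path,
                flatten: bool = False) -> None:
    """Write the model in the BoolNet ``targets, factors`` format.

    BoolNet has no time-delay construct, so a model containing THR terms is
    refused unless ``flatten=True``, which replaces every ``THR_X[tag]`` by a
    plain reference to ``X`` — a documented lossy export.  Hyphens in node
    names are mapped to underscores for BoolNet compatibility.
    """
    if model.has_delays() and not flatten:
        raise ValueError(
            "model contains THR delay terms; pass flatten=True for a "
            "delay-free (lossy) BoolNet export")

    from .rules import And, Not, Or, Thr, Var

    def rename(expr):
        if isinstance(expr, Var):
            return Var(_bnet_name(expr.name))
        if isinstance(expr, Thr):
            return Thr(_bnet_name(expr.name), expr.tag)
        if isinstance(expr, Not):
            return Not(rename(expr.child))
        if isinstance(expr, And):
            return And(tuple(rename(c) for c in expr.children))
        if isinstance(expr, Or):
            return Or(tuple(rename(c) for c in expr.children))
        return expr

    def render(name: str) -> str:
        expr = model.rules[name]
        if flatten:
            expr = flatten_delays(expr)
        return serialize(rename(expr))

    with open(path, "w") as fh:
        fh.write("targets, factors\n")
        for n in model.nodes:
            fh.write(f"{_bnet_name(n)}, {render(n)}\n")


def import_bnet(path: str | Path, **kwargs) -> BooleanModel:
    """Read a delay-free BoolNet ``targets, factors`` file back into a model."""
    lines = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("targets"):
            continue
        target, factors = line.split(",", 1)
        lines.append(f"{target.strip()} = {factors.strip()}")
    return BooleanModel.from_rules("\n".join(lines), **kwargs)
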