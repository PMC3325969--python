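"""Signed regulatory networks and their compilation into Boolean rules.

A network is a set of named nodes connected by signed directed edges
(activation or inhibition).  The module reads and writes a SIF-like
three-column TSV dialect, validates networks, supports edge-specific
("edgetic") deletion, and compiles a network into per-node
activator/inhibitor sets under inhibitor-dominant update semantics:

    next(x) = (OR of activators; TRUE if x has inhibitors but no
               activators) AND NOT (OR of inhibitors)

and a node with no regulators at all updates to FALSE (its continuous
analogue decays to 0).  Any active inhibitor therefore shuts a node off
regardless of its activators.

It also houses the canonical six-node EMT core circuit coupling the
miR-203/SNAI1 and miR-200/ZEB double-negative feedback loops, with
E-cadherin (CDH1) as the epithelial readout.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "NodeClass",
    "Sign",
    "NodeSpec",
    "SignedEdge",
    "NetworkSpec",
    "NodeRule",
    "BooleanRuleSet",
    "NetworkParseError",
    "NetworkValidationError",
    "EdgeNotFoundError",
    "load_network",
    "write_network",
    "emt_core_network",
    "compile_rules",
    "delete_edge",
]


class NodeClass(str, enum.Enum):
    """Annotational node category (miRNA, transcription factor, coding gene)."""

    MIRNA = "miRNA"
    TRANSCRIPTION_FACTOR = "transcription_factor"
    GENE = "gene"


class Sign(str, enum.Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"


#: relation tokens accepted in the SIF-like file dialect
RELATION_TOKENS: Mapping[str, Sign] = {
    "activates": Sign.ACTIVATION,
    "inhibits": Sign.INHIBITION,
}
_SIGN_TO_TOKEN = {v: k for k, v in RELATION_TOKENS.items()}


class NetworkParseError(ValueError):
    """A malformed line in a network or annotation file."""

    def __init__(self, path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class NetworkValidationError(ValueError):
    """The node/edge lists violate a structural invariant."""


class EdgeNotFoundError(KeyError):
    """Requested (source, target) edge does not exist."""


@dataclass(frozen=True)
class NodeSpec:
    id: str
    node_class: NodeClass | None = None

    def __post_init__(self):
        if not self.id:
            raise NetworkValidationError("node id must be nonempty")


@dataclass(frozen=True)
class SignedEdge:
    source: str
    target: str
    sign: Sign


@dataclass(frozen=True)
class NetworkSpec:
    """A validated signed directed network.

    Invariants enforced at construction: node ids unique, edge endpoints
    resolve to nodes, and at most one edge per ordered (source, target)
    pair.  Self-loops are permitted in general.
    """

    nodes: tuple[NodeSpec, ...]
    edges: tuple[SignedEdge, ...]

    def __post_init__(self):
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate node ids: {dupes}")
        idset = set(ids)
        pairs = set()
        for e in self.edges:
            if e.source not in idset or e.target not in idset:
                raise NetworkValidationError(
                    f"edge ({e.source}, {e.target}) references unknown node"
                )
            if (e.source, e.target) in pairs:
                raise NetworkValidationError(
                    f"duplicate edge for ordered pair ({e.source}, {e.target})"
                )
            pairs.add((e.source, e.target))

    # -- queries ---------------------------------------------------------

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.id for n in self.nodes)

    @property
    def sorted_node_ids(self) -> tuple[str, ...]:
        """Node ids in lexicographic order (the canonical enumeration order)."""
        return tuple(sorted(self.node_ids))

    def regulators(self, node_id: str) -> list[SignedEdge]:
        """Incoming edges of *node_id*."""
        if node_id not in set(self.node_ids):
            raise KeyError(node_id)
        return [e for e in self.edges if e.target == node_id]

    def has_edge(self, source: str, target: str) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    # -- derived structures ----------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id, node_class=n.node_class.value if n.node_class else None)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign.value)
        return g

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [
                    {
                        "id": n.id,
                        "node_class": n.node_class.value if n.node_class else None,
                    }
                    for n in self.nodes
                ],
                "edges": [
                    {"source": e.source, "target": e.target, "sign": e.sign.value}
                    for e in self.edges
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        obj = json.loads(text)
        nodes = tuple(
            NodeSpec(d["id"], NodeClass(d["node_class"]) if d.get("node_class") else None)
            for d in obj["nodes"]
        )
        edges = tuple(
            SignedEdge(d["source"], d["target"], Sign(d["sign"])) for d in obj["edges"]
        )
        return cls(nodes, edges)


@dataclass(frozen=True)
class NodeRule:
    """Activator/inhibitor partition of one node's regulators."""

    activators: frozenset[str]
    inhibitors: frozenset[str]


@dataclass(frozen=True)
class BooleanRuleSet:
    """Per-node inhibitor-dominant Boolean update rules.

    ``node_order`` fixes the lexicographic node ordering used by every
    enumeration and every serialized state.
    """

    rules: Mapping[str, NodeRule]
    node_order: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not self.node_order:
            object.__setattr__(self, "node_order", tuple(sorted(self.rules)))
        for node, rule in self.rules.items():
            if rule.activators & rule.inhibitors:
                raise NetworkValidationError(
                    f"node {node}: a regulator cannot be both activator and inhibitor"
                )

    def evaluate(self, node: str, state: Mapping[str, int]) -> int:
        """Inhibitor-dominant update of a single node given a Boolean state."""
        rule = self.rules[node]
        if not rule.activators and not rule.inhibitors:
            return 0
        if rule.activators:
            drive = any(state[a] for a in rule.activators)
        else:  # inhibitors only: active unless inhibited
            drive = True
        inhibited = any(state[b] for b in rule.inhibitors)
        return int(drive and not inhibited)


# ---------------------------------------------------------------------------
# file I/O (SIF-like TSV dialect)
# ---------------------------------------------------------------------------


def load_network(path, annotation_path=None) -> NetworkSpec:
    """Read a network from a SIF-like text file.

    Each non-comment, non-blank line is ``source<TAB>relation<TAB>target``
    with relation in {activates, inhibits}; ``#`` starts a comment line.
    An optional two-column TSV sidecar supplies node classes (id, class);
    annotated-only nodes are added to the node set.
    """
    path = Path(path)
    edges: list[SignedEdge] = []
    node_ids: list[str] = []
    seen: set[str] = set()

    def note(nid: str):
        if nid not in seen:
            seen.add(nid)
            node_ids.append(nid)

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise NetworkParseError(
                    path, lineno, f"expected 3 tab-separated fields, got {len(parts)}"
                )
            source, relation, target = (p.strip() for p in parts)
            if relation not in RELATION_TOKENS:
                raise NetworkParseError(
                    path, lineno, f"unknown relation token {relation!r}"
                )
            if not source or not target:
                raise NetworkParseError(path, lineno, "empty node id")
            note(source)
            note(target)
            edges.append(SignedEdge(source, target, RELATION_TOKENS[relation]))

    classes: dict[str, NodeClass] = {}
    if annotation_path is not None:
        apath = Path(annotation_path)
        with open(apath, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise NetworkParseError(
                        apath, lineno, f"expected 2 tab-separated fields, got {len(parts)}"
                    )
                nid, cls = (p.strip() for p in parts)
                try:
                    classes[nid] = NodeClass(cls)
                except ValueError:
                    raise NetworkParseError(
                        apath, lineno, f"unknown node class {cls!r}"
                    ) from None
                note(nid)

    nodes = tuple(NodeSpec(nid, classes.get(nid)) for nid in node_ids)
    return NetworkSpec(nodes, tuple(edges))


def write_network(net: NetworkSpec, path, annotation_path=None) -> None:
    """Write *net* in the SIF-like dialect (and optionally its annotations)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in net.edges:
            fh.write(f"{e.source}\t{_SIGN_TO_TOKEN[e.sign]}\t{e.target}\n")
        # isolated nodes cannot be expressed as edges; keep them as comments
        targets = {e.source for e in net.edges} | {e.target for e in net.edges}
        for n in net.nodes:
            if n.id not in targets:
                fh.write(f"# node\t{n.id}\n")
    if annotation_path is not None:
        with open(annotation_path, "w", encoding="utf-8") as fh:
            for n in net.nodes:
                if n.node_class is not None:
                    fh.write(f"{n.id}\t{n.node_class.value}\n")


# ---------------------------------------------------------------------------
# the EMT core circuit
# ---------------------------------------------------------------------------


def emt_core_network() -> NetworkSpec:
    """The six-node EMT core circuit.

    SNAI1 represses both miR-200 clusters (collapsed into one miR200 node)
    and miR-203, and activates ZEB1/ZEB2; the ZEB factors and the miRNAs
    repress each other reciprocally; miR-203 represses SNAI1 (closing the
    miR-203/SNAI1 double-negative loop) and ZEB2; E-cadherin (CDH1) is
    repressed by SNAI1 and both ZEB factors and serves as the epithelial
    marker gene.
    """
    TF = NodeClass.TRANSCRIPTION_FACTOR
    MI = NodeClass.MIRNA
    nodes = (
        NodeSpec("SNAI1", TF),
        NodeSpec("ZEB1", TF),
        NodeSpec("ZEB2", TF),
        NodeSpec("miR203", MI),
        NodeSpec("miR200", MI),
        NodeSpec("CDH1", NodeClass.GENE),
    )
    A, I = Sign.ACTIVATION, Sign.INHIBITION
    edges = (
        SignedEdge("SNAI1", "miR203", I),
        SignedEdge("SNAI1", "miR200", I),
        SignedEdge("SNAI1", "ZEB1", A),
        SignedEdge("SNAI1", "ZEB2", A),
        SignedEdge("miR203", "SNAI1", I),
        SignedEdge("miR203", "ZEB2", I),
        SignedEdge("miR200", "ZEB1", I),
        SignedEdge("miR200", "ZEB2", I),
        SignedEdge("ZEB1", "miR203", I),
        SignedEdge("ZEB2", "miR203", I),
        SignedEdge("ZEB1", "miR200", I),
        SignedEdge("ZEB2", "miR200", I),
        SignedEdge("SNAI1", "CDH1", I),
        SignedEdge("ZEB1", "CDH1", I),
        SignedEdge("ZEB2", "CDH1", I),
    )
    return NetworkSpec(nodes, edges)


# ---------------------------------------------------------------------------
# rule compilation and edgetic perturbation
# ---------------------------------------------------------------------------


def compile_rules(net: NetworkSpec) -> BooleanRuleSet:
    """Partition each node's regulators by edge sign into a rule set."""
    rules: dict[str, NodeRule] = {}
    for nid in net.node_ids:
        act = frozenset(
            e.source for e in net.edges if e.target == nid and e.sign is Sign.ACTIVATION
        )
        inh = frozenset(
            e.source for e in net.edges if e.target == nid and e.sign is Sign.INHIBITION
        )
        rules[nid] = NodeRule(act, inh)
    return BooleanRuleSet(rules, tuple(sorted(net.node_ids)))


def delete_edge(net: NetworkSpec, source: str, target: str) -> NetworkSpec:
    """Return a copy of *net* with the (source, target) edge removed.

    The edgetic perturbation primitive: nodes are untouched, exactly one
    edge disappears.
    """
    if not net.has_edge(source, target):
        raise EdgeNotFoundError(f"no edge ({source}, {target})")
    kept = tuple(e for e in net.edges if not (e.source == source and e.target == target))
    return NetworkSpec(net.nodes, kept)
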