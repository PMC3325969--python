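"""Discrete dynamics of Boolean regulatory networks.

Synchronous and asynchronous updating, exhaustive attractor enumeration
over the full state-transition graph (networks up to 20 nodes), basin
sizes, E/M labelling of fixed points, and a Monte-Carlo robustness
procedure: flip one node of an attractor state, relax under random
asynchronous updates, and record where the system lands.  The resulting
attractor-to-attractor transition matrix quantifies how likely the
network is to switch states without an external stimulus.

States are exposed as ``{node id: 0/1}`` mappings; internally they are
packed into integers (bit i = node i in lexicographic order) so that the
2^n sweep and the Monte-Carlo relaxations stay fast.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import BooleanRuleSet, NetworkSpec

__all__ = [
    "StateVector",
    "Attractor",
    "RobustnessReport",
    "CapacityError",
    "StateDomainError",
    "step_synchronous",
    "step_asynchronous",
    "enumerate_fixed_points",
    "enumerate_attractors_synchronous",
    "label_attractors",
    "perturbation_transition_probabilities",
]

StateVector = dict  # mapping node id -> {0, 1}

#: exhaustive enumeration is capped at 2^20 states
MAX_EXHAUSTIVE_NODES = 20


class CapacityError(ValueError):
    """Network too large for exhaustive 2^n enumeration; sample instead."""


class StateDomainError(ValueError):
    """State domain does not match the rule set's node set."""


@dataclass(frozen=True)
class Attractor:
    """A fixed point (one state) or a synchronous cycle (>=2 states).

    ``states`` are ordered so that the synchronous update maps each one
    to the next, cyclically.  Only fixed points ever carry an E/M label.
    """

    kind: str  # "fixed_point" | "cycle"
    states: tuple[Mapping[str, int], ...]
    label: str | None = None

    def __post_init__(self):
        if self.kind == "fixed_point" and len(self.states) != 1:
            raise ValueError("fixed_point attractor must hold exactly one state")
        if self.kind == "cycle" and len(self.states) < 2:
            raise ValueError("cycle attractor must hold at least two states")


@dataclass(frozen=True)
class RobustnessReport:
    """Per-flip return probabilities and the attractor transition matrix.

    ``transition_matrix`` has one row per source attractor and one column
    per destination attractor plus a final "unresolved" column for trials
    that exceeded the step cap; every row sums to 1.
    """

    attractor_names: tuple[str, ...]
    return_probabilities: Mapping[str, Mapping[str, float]]
    transition_matrix: np.ndarray
    trials: int
    seed: int
    step_cap: int

    def row(self, name: str) -> np.ndarray:
        return self.transition_matrix[self.attractor_names.index(name)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "attractors": list(self.attractor_names),
                "columns": list(self.attractor_names) + ["unresolved"],
                "transition_matrix": self.transition_matrix.tolist(),
                "return_probabilities": {
                    k: dict(v) for k, v in self.return_probabilities.items()
                },
                "trials": self.trials,
                "seed": self.seed,
                "step_cap": self.step_cap,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# integer packing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Masks:
    """Bitmask form of a rule set: node i is bit i in lexicographic order."""

    order: tuple[str, ...]
    act: tuple[int, ...]
    inh: tuple[int, ...]
    has_act: tuple[bool, ...]
    has_inh: tuple[bool, ...]


def _compile_masks(rules: BooleanRuleSet) -> _Masks:
    order = tuple(sorted(rules.node_order))
    idx = {n: i for i, n in enumerate(order)}
    act, inh, ha, hi = [], [], [], []
    for n in order:
        r = rules.rules[n]
        a = sum(1 << idx[s] for s in r.activators)
        b = sum(1 << idx[s] for s in r.inhibitors)
        act.append(a)
        inh.append(b)
        ha.append(bool(r.activators))
        hi.append(bool(r.inhibitors))
    return _Masks(order, tuple(act), tuple(inh), tuple(ha), tuple(hi))


def _pack(state: Mapping[str, int], order: Sequence[str]) -> int:
    return sum((1 << i) for i, n in enumerate(order) if state[n])


def _unpack(s: int, order: Sequence[str]) -> StateVector:
    return {n: (s >> i) & 1 for i, n in enumerate(order)}


def _step_int(m: _Masks, s: int) -> int:
    out = 0
    for i in range(len(m.order)):
        if m.has_act[i]:
            drive = (s & m.act[i]) != 0
        else:
            drive = m.has_inh[i]  # inhibitor-only node defaults on; input-free off
        if drive and not (s & m.inh[i]):
            out |= 1 << i
    return out


def _check_domain(rules: BooleanRuleSet, state: Mapping[str, int]) -> None:
    if set(state) != set(rules.node_order):
        raise StateDomainError(
            f"state domain {sorted(state)} != rule domain {sorted(rules.node_order)}"
        )


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------


def step_synchronous(rules: BooleanRuleSet, state: StateVector) -> StateVector:
    """Update every node simultaneously under inhibitor-dominant logic."""
    _check_domain(rules, state)
    return {n: rules.evaluate(n, state) for n in rules.node_order}


def step_asynchronous(
    rules: BooleanRuleSet, state: StateVector, rng: np.random.Generator
) -> StateVector:
    """Update exactly one uniformly chosen node; reproducible from *rng*."""
    _check_domain(rules, state)
    order = tuple(sorted(rules.node_order))
    node = order[int(rng.integers(len(order)))]
    out = dict(state)
    out[node] = rules.evaluate(node, state)
    return out


# ---------------------------------------------------------------------------
# exhaustive enumeration
# ---------------------------------------------------------------------------


def _require_capacity(rules: BooleanRuleSet) -> None:
    n = len(rules.node_order)
    if n > MAX_EXHAUSTIVE_NODES:
        raise CapacityError(
            f"{n} nodes exceeds the exhaustive 2^{MAX_EXHAUSTIVE_NODES} sweep; "
            "use Monte-Carlo sampling instead"
        )


def _successor_table(m: _Masks) -> np.ndarray:
    """Synchronous successor of every state, vectorised over all 2^n states."""
    n = len(m.order)
    states = np.arange(1 << n, dtype=np.int64)
    succ = np.zeros(1 << n, dtype=np.int64)
    for i in range(n):
        if m.has_act[i]:
            drive = (states & m.act[i]) != 0
        else:
            drive = np.full(states.shape, m.has_inh[i])
        bit = drive & ((states & m.inh[i]) == 0)
        succ |= bit.astype(np.int64) << i
    return succ


def enumerate_fixed_points(rules: BooleanRuleSet) -> list[StateVector]:
    """All states with step_synchronous(s) == s, exhaustively, in order.

    Fixed points are scheme-independent: they are equilibria under any
    update schedule.
    """
    _require_capacity(rules)
    m = _compile_masks(rules)
    if not m.order:
        return [{}] if _step_int(m, 0) == 0 else []
    succ = _successor_table(m)
    fps = [_unpack(int(s), m.order) for s in
           np.flatnonzero(succ == np.arange(succ.size))]
    fps.sort(key=lambda s: tuple(s[n] for n in m.order))
    return fps


def enumerate_attractors_synchronous(
    rules: BooleanRuleSet,
) -> tuple[list[Attractor], list[int]]:
    """All synchronous attractors with their basin sizes.

    Every one of the 2^n states drains into exactly one attractor, so the
    basin sizes sum to 2^n.  Fixed points come first, then cycles; within
    each kind, attractors are ordered by their smallest packed state.
    """
    _require_capacity(rules)
    m = _compile_masks(rules)
    n = len(m.order)
    if n == 0:
        return [Attractor("fixed_point", ({},))], [1]
    succ = _successor_table(m)
    size = succ.size

    # colour[s]: -1 unknown, else attractor index
    colour = np.full(size, -1, dtype=np.int64)
    cycles: list[list[int]] = []  # attractor id -> ordered cycle states
    for s0 in range(size):
        if colour[s0] != -1:
            continue
        path = []
        on_path: dict[int, int] = {}
        s = s0
        while colour[s] == -1 and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = int(succ[s])
        if colour[s] != -1:
            aid = int(colour[s])
        else:  # found a new cycle starting at path position on_path[s]
            start = on_path[s]
            cyc = path[start:]
            # rotate so the cycle begins at its lexicographically smallest state
            def lex(p):
                return tuple((p >> i) & 1 for i in range(n))

            k = min(range(len(cyc)), key=lambda j: lex(cyc[j]))
            cycles.append(cyc[k:] + cyc[:k])
            aid = len(cycles) - 1
        for s in path:
            colour[s] = aid

    # reorder: fixed points first, then cycles, each lexicographically
    def lex_key(p):
        return tuple((p >> i) & 1 for i in range(n))

    ids = sorted(
        range(len(cycles)),
        key=lambda a: (len(cycles[a]) > 1, lex_key(cycles[a][0])),
    )
    remap = {old: new for new, old in enumerate(ids)}
    attractors = []
    for old in ids:
        cyc = cycles[old]
        kind = "fixed_point" if len(cyc) == 1 else "cycle"
        attractors.append(Attractor(kind, tuple(_unpack(s, m.order) for s in cyc)))
    basin = [0] * len(attractors)
    counts = np.bincount(colour, minlength=len(cycles))
    for old, c in enumerate(counts):
        basin[remap[old]] = int(c)
    return attractors, basin


def label_attractors(
    attractors: Sequence[Attractor], net: NetworkSpec
) -> list[Attractor]:
    """Attach phenotype labels to fixed points.

    "E" (epithelial): CDH1 on, SNAI1 off.  "M" (mesenchymal): SNAI1 on,
    CDH1 off.  Cycles and non-matching fixed points stay unlabeled.
    """
    ids = set(net.node_ids)
    if "CDH1" not in ids or "SNAI1" not in ids:
        warnings.warn(
            "network lacks CDH1/SNAI1 marker nodes; E/M labelling skipped",
            stacklevel=2,
        )
        return list(attractors)
    out = []
    for a in attractors:
        label = None
        if a.kind == "fixed_point":
            s = a.states[0]
            if s["CDH1"] == 1 and s["SNAI1"] == 0:
                label = "E"
            elif s["SNAI1"] == 1 and s["CDH1"] == 0:
                label = "M"
        out.append(Attractor(a.kind, a.states, label))
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo robustness
# ---------------------------------------------------------------------------


def _attractor_name(a: Attractor, i: int) -> str:
    return a.label if a.label else f"attractor_{i}"


def _async_closed(m: _Masks, state_set: frozenset[int]) -> bool:
    """True iff every single-node update from every member stays inside."""
    n = len(m.order)
    for s in state_set:
        for i in range(n):
            if m.has_act[i]:
                drive = (s & m.act[i]) != 0
            else:
                drive = m.has_inh[i]
            bit = 1 if (drive and not (s & m.inh[i])) else 0
            t = (s & ~(1 << i)) | (bit << i)
            if t not in state_set:
                return False
    return True


def perturbation_transition_probabilities(
    rules: BooleanRuleSet,
    attractors: Sequence[Attractor],
    trials: int = 1000,
    seed: int = 0,
    step_cap: int | None = None,
) -> RobustnessReport:
    """Single-node-flip robustness of each attractor under async relaxation.

    For every state of every attractor and every node, the node is
    flipped and the perturbed state relaxed by uniformly random
    single-node updates until it is absorbed by an attractor or the step
    cap (default 10 * 2^n) is hit; capped trials land in an explicit
    "unresolved" column.  A relaxation is absorbed only by attractors
    whose state set is closed under asynchronous updates (always true
    for fixed points); results aggregate to per-flip return
    probabilities and an attractor-to-attractor transition matrix, fully
    reproducible from *seed*.
    """
    if not attractors:
        raise ValueError("attractors must be nonempty")
    if trials < 1:
        raise ValueError("trials must be >= 1")
    m = _compile_masks(rules)
    n = len(m.order)
    if step_cap is None:
        step_cap = 10 * (1 << n)
    names = tuple(_attractor_name(a, i) for i, a in enumerate(attractors))

    # absorbing map: packed state -> attractor index, for async-closed attractors
    absorbing: dict[int, int] = {}
    for ai, a in enumerate(attractors):
        packed = frozenset(_pack(s, m.order) for s in a.states)
        if _async_closed(m, packed):
            for p in packed:
                absorbing[p] = ai

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(attractors), len(attractors) + 1), dtype=np.int64)
    return_probs: dict[str, dict[str, float]] = {}

    for ai, a in enumerate(attractors):
        per_node_return: dict[str, float] = {}
        for i, node in enumerate(m.order):
            returned = 0
            total = 0
            for s0 in a.states:
                start = _pack(s0, m.order) ^ (1 << i)
                for _ in range(trials):
                    s = start
                    dest = -1
                    for _ in range(step_cap):
                        hit = absorbing.get(s)
                        if hit is not None:
                            dest = hit
                            break
                        j = int(rng.integers(n))
                        if m.has_act[j]:
                            drive = (s & m.act[j]) != 0
                        else:
                            drive = m.has_inh[j]
                        bit = 1 if (drive and not (s & m.inh[j])) else 0
                        s = (s & ~(1 << j)) | (bit << j)
                    else:
                        hit = absorbing.get(s)
                        if hit is not None:
                            dest = hit
                    if dest == -1:
                        counts[ai, -1] += 1
                    else:
                        counts[ai, dest] += 1
                        if dest == ai:
                            returned += 1
                    total += 1
            per_node_return[node] = returned / total if total else float("nan")
        return_probs[names[ai]] = per_node_return

    row_sums = counts.sum(axis=1, keepdims=True)
    matrix = counts / np.where(row_sums == 0, 1, row_sums)
    return RobustnessReport(
        attractor_names=names,
        return_probabilities=return_probs,
        transition_matrix=matrix,
        trials=trials,
        seed=seed,
        step_cap=step_cap,
    )
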