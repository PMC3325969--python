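"""Continuous transformation of the Boolean model and stimulus experiments.

The Boolean network is mapped to a coupled ODE system on the unit cube:
each node carries an activation level x in [0, 1], its regulators are
summarised into a normalised combined input omega in [0, 1], and

    dx/dt = f(omega; h) - gamma * x

with f a normalised sigmoid of steepness h satisfying f(0) = 0,
f(1/2) = 1/2 and f(1) = 1.  The mapping preserves the logical structure:
with gamma = 1 every Boolean fixed point embeds as a continuous steady
state at the corresponding 0/1 corner, while the smooth dynamics make
time-resolved stimulus experiments possible — in particular the SNAI1
pulse that drives the epithelial state into the mesenchymal one.

Integration uses scipy's LSODA; clamping events (a node held at a fixed
level over a time window) split the integration into segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import BooleanRuleSet, NetworkSpec, compile_rules, delete_edge
from .boolean import enumerate_fixed_points

__all__ = [
    "OdeParameters",
    "ClampEvent",
    "StimulusProtocol",
    "TimeCourse",
    "SteadyStateResult",
    "EdgeticReport",
    "IntegrationError",
    "combined_input",
    "node_rate",
    "simulate",
    "find_steady_states",
    "edgetic_experiment",
]


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last valid state and time."""

    def __init__(self, message: str, t: float, state: Mapping[str, float]):
        super().__init__(f"{message} (t={t:g})")
        self.t = t
        self.state = dict(state)


@dataclass(frozen=True)
class OdeParameters:
    """Parameters of the continuous transformation.

    gain
        sigmoid steepness h (dimensionless); h >= 10 keeps the continuous
        steady states in tight correspondence with the Boolean fixed points.
    decay
        first-order decay rate gamma (1/time), shared by all nodes unless
        ``decay_per_node`` overrides individual nodes.
    t_end
        default simulation horizon (arbitrary time units).
    threshold
        level above which a node counts as ON when discretising a
        continuous state back to a Boolean one.
    velocity_tol
        infinity-norm of dx/dt below which a relaxed state is accepted
        as a steady state.
    """

    gain: float = 10.0
    decay: float = 1.0
    decay_per_node: Mapping[str, float] = field(default_factory=dict)
    t_end: float = 20.0
    rtol: float = 1e-8
    atol: float = 1e-10
    threshold: float = 0.5
    velocity_tol: float = 1e-6
    sample_step: float = 0.05

    def __post_init__(self):
        if self.gain <= 0 or self.decay <= 0 or self.t_end <= 0:
            raise ValueError("gain, decay and t_end must be positive")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.velocity_tol <= 0 or self.sample_step <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class ClampEvent:
    node: str
    value: float
    start: float
    duration: float

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("clamp duration must be positive")
        if not (0.0 <= self.value <= 1.0):
            raise ValueError("clamp value must lie in [0, 1]")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered list of clamping events; events on one node may not overlap."""

    events: tuple[ClampEvent, ...] = ()

    def __post_init__(self):
        per_node: dict[str, list[ClampEvent]] = {}
        for e in self.events:
            per_node.setdefault(e.node, []).append(e)
        for node, evs in per_node.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping clamp events on node {node}")

    def boundaries(self) -> list[float]:
        ts = {e.start for e in self.events} | {e.end for e in self.events}
        return sorted(ts)

    def active_at(self, t: float) -> dict[str, float]:
        return {e.node: e.value for e in self.events if e.start <= t < e.end}


@dataclass(frozen=True)
class TimeCourse:
    times: np.ndarray
    values: pd.DataFrame  # index = times, columns = node ids
    protocol: StimulusProtocol

    @property
    def final_state(self) -> dict[str, float]:
        return self.values.iloc[-1].to_dict()

    def thresholded_final(self, threshold: float = 0.5) -> dict[str, int]:
        return {n: int(v > threshold) for n, v in self.final_state.items()}

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "time", self.times)
        out.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady states of the continuous system with Boolean labels attached."""

    states: list[dict[str, float]]
    labels: list[str | None]
    boolean_projections: list[dict[str, int]]
    unconverged: int
    seed: int

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class EdgeticReport:
    """Steady states before vs after deleting one edge."""

    source: str
    target: str
    before: SteadyStateResult
    after: SteadyStateResult
    persisted: list[bool]  # for each 'before' state: survives the deletion?

    @property
    def count_before(self) -> int:
        return len(self.before)

    @property
    def count_after(self) -> int:
        return len(self.after)


# ---------------------------------------------------------------------------
# the transformation itself
# ---------------------------------------------------------------------------


def combined_input(
    state: Mapping[str, float],
    activators: Sequence[str] | frozenset,
    inhibitors: Sequence[str] | frozenset,
) -> float:
    """Normalised combined regulatory input omega in [0, 1].

    With n activators at levels x_a, A = ((1+n)/n) * S/(1+S) where
    S = sum(x_a); A saturates at 1 when every activator is fully on and
    is taken as 1 when a node has inhibitors but no activators.  B is
    the symmetric expression over the m inhibitors (0 if none).  Then
    omega = A * (1 - B); a node with no regulators at all has omega = 0.
    """
    acts = sorted(activators)
    inhs = sorted(inhibitors)
    if not acts and not inhs:
        return 0.0
    if acts:
        s = sum(state[a] for a in acts)
        n = len(acts)
        A = ((1 + n) / n) * s / (1 + s)
    else:
        A = 1.0
    if inhs:
        s = sum(state[b] for b in inhs)
        m = len(inhs)
        B = ((1 + m) / m) * s / (1 + s)
    else:
        B = 0.0
    return A * (1.0 - B)


def _production(omega: float, h: float) -> float:
    # normalised sigmoid: 0 at omega=0, 1/2 at omega=1/2, 1 at omega=1
    e_half = exp(0.5 * h)
    e_om = exp(-h * (omega - 0.5))
    return (-e_half + e_om) / ((1.0 - e_half) * (1.0 + e_om))


def node_rate(x: float, omega: float, h: float, gamma: float) -> float:
    """dx/dt of one node: sigmoidal production minus linear decay."""
    return _production(omega, h) - gamma * x


def _build_rhs(rules: BooleanRuleSet, params: OdeParameters, clamped: Mapping[str, float]):
    order = tuple(sorted(rules.node_order))
    idx = {n: i for i, n in enumerate(order)}
    acts = [tuple(idx[a] for a in sorted(rules.rules[n].activators)) for n in order]
    inhs = [tuple(idx[b] for b in sorted(rules.rules[n].inhibitors)) for n in order]
    gamma = np.array(
        [params.decay_per_node.get(n, params.decay) for n in order], dtype=float
    )
    h = params.gain
    clamp_idx = {idx[n]: v for n, v in clamped.items()}

    def rhs(t, y):
        dy = np.empty_like(y)
        for i in range(len(order)):
            if i in clamp_idx:
                dy[i] = 0.0
                continue
            a_idx, b_idx = acts[i], inhs[i]
            if not a_idx and not b_idx:
                omega = 0.0
            else:
                if a_idx:
                    s = float(sum(y[j] for j in a_idx))
                    n = len(a_idx)
                    A = ((1 + n) / n) * s / (1 + s)
                else:
                    A = 1.0
                if b_idx:
                    s = float(sum(y[j] for j in b_idx))
                    m = len(b_idx)
                    B = ((1 + m) / m) * s / (1 + s)
                else:
                    B = 0.0
                omega = A * (1.0 - B)
            dy[i] = _production(omega, h) - gamma[i] * y[i]
        return dy

    return order, rhs


def simulate(
    net: NetworkSpec,
    params: OdeParameters,
    initial: Mapping[str, float],
    protocol: StimulusProtocol = StimulusProtocol(),
) -> TimeCourse:
    """Integrate the continuous system under a clamping protocol.

    Clamped nodes are held constant during their events; integration is
    split at event boundaries and sampled on a uniform grid (plus the
    boundaries themselves).  Deterministic for fixed parameters.
    """
    rules = compile_rules(net)
    order = tuple(sorted(net.node_ids))
    if set(initial) != set(order):
        raise ValueError("initial state domain does not match the network")
    for e in protocol.events:
        if e.node not in set(order):
            raise ValueError(f"protocol clamps unknown node {e.node}")

    t_end = params.t_end
    cuts = [0.0] + [t for t in protocol.boundaries() if 0.0 < t < t_end] + [t_end]
    y = np.array([float(initial[n]) for n in order])

    all_t: list[float] = []
    all_y: list[np.ndarray] = []
    for t0, t1 in zip(cuts, cuts[1:]):
        clamped = protocol.active_at(t0)
        _, rhs = _build_rhs(rules, params, clamped)
        idx = {n: i for i, n in enumerate(order)}
        for n, v in clamped.items():
            y[idx[n]] = v
        grid = np.arange(t0, t1, params.sample_step)
        t_eval = np.unique(np.concatenate([grid, [t0, t1]]))
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
            rtol=params.rtol, atol=params.atol,
        )
        if not sol.success:
            last = {n: float(v) for n, v in zip(order, y)}
            raise IntegrationError(sol.message, t0, last)
        skip = 1 if all_t else 0  # drop duplicated boundary sample
        all_t.extend(sol.t[skip:])
        all_y.extend(sol.y.T[skip:])
        y = sol.y[:, -1].copy()

    times = np.array(all_t)
    values = pd.DataFrame(np.vstack(all_y), index=times, columns=order)
    return TimeCourse(times=times, values=values, protocol=protocol)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------


def _relax(rules, params, y0, order, horizon):
    _, rhs = _build_rhs(rules, params, {})
    sol = solve_ivp(
        rhs, (0.0, horizon), y0, method="LSODA",
        rtol=params.rtol, atol=params.atol,
    )
    if not sol.success:
        return None, None
    y = sol.y[:, -1]
    v = rhs(horizon, y)
    return y, float(np.max(np.abs(v)))


def find_steady_states(
    net: NetworkSpec,
    params: OdeParameters | None = None,
    n_restarts: int = 100,
    seed: int = 0,
    horizon: float = 200.0,
    dedup_resolution: float = 0.05,
) -> SteadyStateResult:
    """Steady states found by relaxation from Boolean corners + random starts.

    Every synchronous Boolean fixed point (embedded as a 0/1 vector) and
    ``n_restarts`` uniformly random initial conditions are relaxed to
    *horizon*; states whose velocity infinity-norm falls below
    ``params.velocity_tol`` are kept, deduplicated at *dedup_resolution*
    per coordinate, and discretised at ``params.threshold`` for
    labelling.  Non-convergent relaxations are counted, never dropped.
    """
    params = params or OdeParameters()
    rules = compile_rules(net)
    order = tuple(sorted(net.node_ids))
    rng = np.random.default_rng(seed)

    starts = [
        np.array([float(fp[n]) for n in order])
        for fp in enumerate_fixed_points(rules)
    ]
    starts.extend(rng.uniform(0.0, 1.0, size=len(order)) for _ in range(n_restarts))

    found: list[np.ndarray] = []
    unconverged = 0
    for y0 in starts:
        y, vel = _relax(rules, params, y0, order, horizon)
        if y is None or vel is None or vel > params.velocity_tol:
            unconverged += 1
            continue
        if not any(np.max(np.abs(y - f)) < dedup_resolution for f in found):
            found.append(y)

    # deterministic ordering: by discretised pattern, then by values
    found.sort(key=lambda y: tuple(np.round(y, 6)))
    states = [{n: float(v) for n, v in zip(order, y)} for y in found]
    projections = [
        {n: int(v > params.threshold) for n, v in s.items()} for s in states
    ]
    labels: list[str | None] = []
    marker_ok = {"CDH1", "SNAI1"} <= set(order)
    for proj in projections:
        label = None
        if marker_ok:
            if proj["CDH1"] == 1 and proj["SNAI1"] == 0:
                label = "E"
            elif proj["SNAI1"] == 1 and proj["CDH1"] == 0:
                label = "M"
        labels.append(label)
    return SteadyStateResult(states, labels, projections, unconverged, seed)


def edgetic_experiment(
    net: NetworkSpec,
    params: OdeParameters | None = None,
    source: str = "miR203",
    target: str = "SNAI1",
    n_restarts: int = 100,
    seed: int = 0,
) -> EdgeticReport:
    """Compare continuous steady states before and after deleting one edge."""
    params = params or OdeParameters()
    before = find_steady_states(net, params, n_restarts=n_restarts, seed=seed)
    after = find_steady_states(
        delete_edge(net, source, target), params, n_restarts=n_restarts, seed=seed
    )
    order = tuple(sorted(net.node_ids))
    persisted = []
    for s in before.states:
        v = np.array([s[n] for n in order])
        persisted.append(
            any(
                np.max(np.abs(v - np.array([t[n] for n in order]))) < 0.05
                for t in after.states
            )
        )
    return EdgeticReport(source, target, before, after, persisted)
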