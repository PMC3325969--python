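"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (truth-table sweeps over dicts,
direct statistical formulas) that share no code with the package's
optimised paths.
"""

import itertools
import math

import numpy as np

from emtnet.network import NetworkSpec, NodeSpec, Sign, SignedEdge


def fixed_points_oracle(net: NetworkSpec) -> list[dict]:
    """Enumerate fixed points by evaluating the inhibitor-dominant truth
    table state by state with plain dict arithmetic."""
    ids = sorted(net.node_ids)
    acts = {n: [e.source for e in net.edges
                if e.target == n and e.sign is Sign.ACTIVATION] for n in ids}
    inhs = {n: [e.source for e in net.edges
                if e.target == n and e.sign is Sign.INHIBITION] for n in ids}
    out = []
    for bits in itertools.product([0, 1], repeat=len(ids)):
        state = dict(zip(ids, bits))
        nxt = {}
        for n in ids:
            a, b = acts[n], inhs[n]
            if not a and not b:
                nxt[n] = 0
            else:
                drive = any(state[x] for x in a) if a else True
                nxt[n] = int(drive and not any(state[x] for x in b))
        if nxt == state:
            out.append(state)
    return out


def welch_t_oracle(x, y):
    """Welch t statistic of mean(x) - mean(y), from the textbook formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx = x.var(ddof=1) / len(x)
    vy = y.var(ddof=1) / len(y)
    return (x.mean() - y.mean()) / math.sqrt(vx + vy)


def pearson_oracle(x, y):
    """Pearson correlation from the definitional sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))


def random_network(rng: np.random.Generator, max_nodes: int = 10) -> NetworkSpec:
    """A random signed network with up to *max_nodes* nodes (self-loops allowed)."""
    n = int(rng.integers(1, max_nodes + 1))
    ids = [f"n{i:02d}" for i in range(n)]
    edges = []
    p = float(rng.uniform(0.1, 0.5))
    for s in ids:
        for t in ids:
            if rng.random() < p:
                sign = Sign.ACTIVATION if rng.random() < 0.5 else Sign.INHIBITION
                edges.append(SignedEdge(s, t, sign))
    return NetworkSpec(tuple(NodeSpec(i) for i in ids), tuple(edges))
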