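"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the data the signature procedures were designed
for, without any download:

* ``generate_em_study`` — an epithelial/mesenchymal log-intensity study
  with planted UP/DOWN miRNAs at a chosen standardised effect size plus
  Gaussian noise (a stand-in for the published epithelial/mesenchymal
  cancer cell line panels);
* ``generate_correlated_module`` — a latent-factor expression matrix in
  which a module containing the miR-200 family and miR-203 shares one
  Gaussian factor (the correlation-ranking test bed);
* ``generate_timecourse_ratios`` — probe-replicated log-ratio tables per
  time point with planted fold changes (the replicate-filter test bed).

All generators are pure functions of their parameters and seed, and
``fixtures()`` bundles the six-node network with its E/M states as the
single source of truth for the dynamic tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkSpec, emt_core_network
from .signatures import ExpressionMatrix, MIR200_FAMILY

__all__ = [
    "PlantedStudyTruth",
    "PlantedModuleTruth",
    "FixtureBundle",
    "generate_em_study",
    "generate_correlated_module",
    "generate_timecourse_ratios",
    "fixtures",
    "mirbase_feature_ids",
]


def mirbase_feature_ids(n: int) -> list[str]:
    """miRBase-style feature universe: the miR-200 family, miR-203, fillers."""
    base = list(MIR200_FAMILY) + ["hsa-miR-203"]
    fillers = [f"hsa-miR-{1000 + i}" for i in range(max(0, n - len(base)))]
    return (base + fillers)[:n]


@dataclass(frozen=True)
class PlantedStudyTruth:
    """Ground truth of a planted E/M study.

    Effect sizes are standardised (in units of the noise scale sigma) and
    applied to mesenchymal samples: positive for planted-UP miRNAs,
    negative for planted-DOWN ones.
    """

    down_ids: frozenset[str]
    up_ids: frozenset[str] = frozenset()
    effect_size: float = 2.0
    sigma: float = 1.0
    n_epithelial: int = 10
    n_mesenchymal: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.down_ids & self.up_ids:
            raise ValueError("planted DOWN and UP sets must be disjoint")
        if self.effect_size == 0 and (self.down_ids or self.up_ids):
            raise ValueError("planted features require a nonzero effect size")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_epithelial < 2 or self.n_mesenchymal < 2:
            raise ValueError("group sizes must be >= 2")


@dataclass(frozen=True)
class PlantedModuleTruth:
    """Ground truth of a planted correlated module (latent-factor model)."""

    member_ids: tuple[str, ...]
    loading: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.loading <= 1.0):
            raise ValueError("loading must lie in (0, 1]")


@dataclass(frozen=True)
class FixtureBundle:
    """The canonical network fixture and its two stable Boolean states."""

    network: NetworkSpec
    sif_text: str
    node_names: tuple[str, ...]
    e_state: Mapping[str, int]
    m_state: Mapping[str, int]


def generate_em_study(
    n_mirna: int,
    truth: PlantedStudyTruth,
) -> ExpressionMatrix:
    """A planted epithelial/mesenchymal log-intensity study.

    log-intensity = baseline + group shift + N(0, sigma^2) noise, with
    the shift effect_size*sigma added to mesenchymal samples of
    planted-UP miRNAs and subtracted for planted-DOWN ones.
    Bit-reproducible from ``truth.seed``.
    """
    features = mirbase_feature_ids(n_mirna)
    unknown = (truth.down_ids | truth.up_ids) - set(features)
    if unknown:
        raise ValueError(f"planted ids outside the feature universe: {sorted(unknown)}")
    rng = np.random.default_rng(truth.seed)
    n_e, n_m = truth.n_epithelial, truth.n_mesenchymal
    baseline = rng.uniform(6.0, 12.0, size=n_mirna)  # typical log2 intensities
    values = baseline[:, None] + rng.normal(
        0.0, truth.sigma, size=(n_mirna, n_e + n_m)
    )
    shift = truth.effect_size * truth.sigma
    for i, f in enumerate(features):
        if f in truth.up_ids:
            values[i, n_e:] += shift
        elif f in truth.down_ids:
            values[i, n_e:] -= shift
    samples = [f"E{i + 1}" for i in range(n_e)] + [f"M{i + 1}" for i in range(n_m)]
    labels = pd.Series(
        ["epithelial"] * n_e + ["mesenchymal"] * n_m, index=samples
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), labels
    )


def generate_correlated_module(
    n_mirna: int,
    n_samples: int,
    truth: PlantedModuleTruth,
    sigma: float = 0.5,
) -> ExpressionMatrix:
    """A latent-factor matrix with one planted co-expression module.

    Module members = loading * (shared standard-normal factor per
    sample) + N(0, sigma^2); non-members are pure noise of matched
    marginal variance.  Reproducible from ``truth.seed``.
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    features = mirbase_feature_ids(n_mirna)
    unknown = set(truth.member_ids) - set(features)
    if unknown:
        raise ValueError(f"module ids outside the feature universe: {sorted(unknown)}")
    rng = np.random.default_rng(truth.seed)
    factor = rng.standard_normal(n_samples)
    members = set(truth.member_ids)
    marginal_sd = float(np.hypot(truth.loading, sigma))
    rows = []
    for f in features:
        if f in members:
            rows.append(truth.loading * factor + rng.normal(0.0, sigma, n_samples))
        else:
            rows.append(rng.normal(0.0, marginal_sd, n_samples))
    samples = [f"S{i + 1}" for i in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(rows, index=features, columns=samples))


def generate_timecourse_ratios(
    n_mirna: int,
    time_points: Sequence[str] = ("72h", "96h"),
    n_replicates: int = 3,
    de_fraction: float = 0.1,
    lfc: float = -1.0,
    sigma: float = 0.1,
    n_probes: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Replicated log-ratio tables per time point with planted fold changes.

    Planted miRNAs (the first ``round(de_fraction * n_mirna)`` feature
    ids) have probe-level ratios centred at *lfc* at every time point;
    the rest are centred at 0.  Each replicate row carries its mean
    log-ratio, a one-sample t-test p-value against 0, and the
    probe-level ratios themselves.  Returns (table, planted ids).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if n_probes < 2:
        raise ValueError("need at least 2 probes per replicate")
    features = mirbase_feature_ids(n_mirna)
    n_planted = int(round(de_fraction * n_mirna))
    planted = frozenset(features[:n_planted]) if lfc != 0 else frozenset()
    rng = np.random.default_rng(seed)
    rows = []
    for f in features:
        centre = lfc if f in planted else 0.0
        for tp in time_points:
            for r in range(1, n_replicates + 1):
                probes = rng.normal(centre, sigma, size=n_probes)
                p = float(stats.ttest_1samp(probes, 0.0).pvalue)
                rows.append((f, tp, r, float(probes.mean()), p, probes.tolist()))
    table = pd.DataFrame(
        rows,
        columns=["mirna", "time_point", "replicate", "log_ratio", "p_value",
                 "probe_ratios"],
    )
    return table, planted


def fixtures() -> FixtureBundle:
    """The network fixture plus the E/M Boolean states, from one source."""
    net = emt_core_network()
    from .network import _SIGN_TO_TOKEN  # same dialect as write_network

    lines = []
    for e in net.edges:
        lines.append(f"{e.source}\t{_SIGN_TO_TOKEN[e.sign]}\t{e.target}")
    sif_text = "\n".join(lines) + "\n"
    e_state = {"SNAI1": 0, "ZEB1": 0, "ZEB2": 0, "miR203": 1, "miR200": 1, "CDH1": 1}
    m_state = {"SNAI1": 1, "ZEB1": 1, "ZEB2": 1, "miR203": 0, "miR200": 0, "CDH1": 0}
    return FixtureBundle(
        network=net,
        sif_text=sif_text,
        node_names=net.node_ids,
        e_state=e_state,
        m_state=m_state,
    )
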