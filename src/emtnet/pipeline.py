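"""Orchestration of the full network and signature analyses.

``run_core_network_analysis`` executes, in order: network load/validate,
rule compilation, exhaustive fixed-point and attractor enumeration, E/M
labelling, Monte-Carlo robustness, continuous steady states, the SNAI1
pulse simulation, and the edgetic deletion experiment, writing TSV/JSON
artifacts plus a provenance block (config hash, seeds, version) so every
report regenerates from its own config.  ``run_signature_analysis`` runs
the per-study signatures, the cross-study consensus and the family
correlation ranking over a list of study matrices.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .network import NetworkSpec, compile_rules, delete_edge, emt_core_network, load_network
from .boolean import (
    enumerate_attractors_synchronous,
    enumerate_fixed_points,
    label_attractors,
    perturbation_transition_probabilities,
)
from .continuous import (
    ClampEvent,
    OdeParameters,
    StimulusProtocol,
    edgetic_experiment,
    find_steady_states,
    simulate,
)
from .signatures import (
    MIR200_FAMILY,
    ExpressionMatrix,
    differential_signature,
    family_correlation_rank,
    intersect_signatures,
)

__all__ = ["RunConfig", "AnalysisReport", "run_core_network_analysis", "run_signature_analysis"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run; every default lands in provenance."""

    network: str = "builtin:emt"
    gain: float = 10.0
    decay: float = 1.0
    t_end: float = 20.0
    trials: int = 1000
    seed: int = 0
    pulse_node: str = "SNAI1"
    pulse_value: float = 1.0
    pulse_start: float = 2.0
    pulse_duration: float = 2.0
    edgetic_source: str = "miR203"
    edgetic_target: str = "SNAI1"
    alpha: float = 0.01
    min_studies: int = 3
    family: tuple[str, ...] = MIR200_FAMILY
    n_restarts: int = 100
    outdir: str = "emtnet-report"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "family" in raw:
            raw["family"] = tuple(raw["family"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Paths and in-memory results of one pipeline run."""

    outdir: Path
    provenance: dict
    results: dict = field(default_factory=dict)


def _log(stage: str, t0: float) -> None:
    print(f"[emtnet] {stage} ({time.perf_counter() - t0:.2f}s)", file=sys.stderr)


def _resolve_network(spec: str) -> NetworkSpec:
    if spec == "builtin:emt":
        return emt_core_network()
    return load_network(spec)


def _attractor_table(attractors, basins) -> pd.DataFrame:
    rows = []
    for i, (a, b) in enumerate(zip(attractors, basins)):
        for j, s in enumerate(a.states):
            rows.append(
                {"attractor": i, "kind": a.kind, "label": a.label or "",
                 "state_index": j, "basin_size": b, **s}
            )
    return pd.DataFrame(rows)


def run_core_network_analysis(config: RunConfig) -> AnalysisReport:
    """The full dynamic workflow on one network; see module docstring."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "version": __version__,
    }
    report = AnalysisReport(outdir=outdir, provenance=provenance)
    t0 = time.perf_counter()
    stage = "load network"
    try:
        net = _resolve_network(config.network)
        rules = compile_rules(net)
        _log(stage, t0)

        stage = "enumerate attractors"
        fps = enumerate_fixed_points(rules)
        attractors, basins = enumerate_attractors_synchronous(rules)
        attractors = label_attractors(attractors, net)
        atable = _attractor_table(attractors, basins)
        atable.to_csv(outdir / "attractors.tsv", sep="\t", index=False)
        report.results["fixed_points"] = fps
        report.results["attractors"] = attractors
        report.results["basins"] = basins
        _log(stage, t0)

        stage = "robustness"
        rob = perturbation_transition_probabilities(
            rules, attractors, trials=config.trials, seed=config.seed
        )
        (outdir / "robustness.json").write_text(rob.to_json())
        report.results["robustness"] = rob
        _log(stage, t0)

        stage = "continuous steady states"
        params = OdeParameters(gain=config.gain, decay=config.decay, t_end=config.t_end)
        ss = find_steady_states(
            net, params, n_restarts=config.n_restarts, seed=config.seed
        )
        ss_rows = [
            {"label": lab or "", **st} for st, lab in zip(ss.states, ss.labels)
        ]
        pd.DataFrame(ss_rows).to_csv(outdir / "steady_states.tsv", sep="\t", index=False)
        report.results["steady_states"] = ss
        _log(stage, t0)

        stage = "pulse simulation"
        e_states = [s for s, lab in zip(ss.states, ss.labels) if lab == "E"]
        if e_states:
            protocol = StimulusProtocol(
                (ClampEvent(config.pulse_node, config.pulse_value,
                            config.pulse_start, config.pulse_duration),)
            )
            tc = simulate(net, params, e_states[0], protocol)
            tc.to_tsv(outdir / "pulse_timecourse.tsv")
            report.results["pulse"] = tc
        _log(stage, t0)

        stage = "edgetic experiment"
        if net.has_edge(config.edgetic_source, config.edgetic_target):
            er = edgetic_experiment(
                net, params, config.edgetic_source, config.edgetic_target,
                n_restarts=config.n_restarts, seed=config.seed,
            )
            (outdir / "edgetic.json").write_text(json.dumps({
                "deleted_edge": [er.source, er.target],
                "count_before": er.count_before,
                "count_after": er.count_after,
                "labels_before": er.before.labels,
                "labels_after": er.after.labels,
                "persisted": er.persisted,
            }, indent=2))
            report.results["edgetic"] = er
        _log(stage, t0)
    except Exception as exc:
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return report


def run_signature_analysis(
    config: RunConfig,
    studies: Sequence[ExpressionMatrix],
) -> AnalysisReport:
    """Per-study signatures, consensus intersection, correlation ranking."""
    if not studies:
        raise ValueError("need at least one study matrix")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "version": __version__,
    }
    report = AnalysisReport(outdir=outdir, provenance=provenance)
    t0 = time.perf_counter()

    signatures = []
    failures = []
    for i, m in enumerate(studies, start=1):
        try:
            sig = differential_signature(m, alpha=config.alpha)
            sig.table.to_csv(outdir / f"signature_study{i}.tsv", sep="\t")
            signatures.append(sig)
        except Exception as exc:  # isolate per-study failures
            failures.append({"study": i, "error": str(exc)})
            print(f"[emtnet] study {i} failed: {exc}", file=sys.stderr)
    _log("per-study signatures", t0)
    if not signatures:
        raise RuntimeError("every study failed; nothing to intersect")

    if config.min_studies > len(signatures):
        print(
            f"[emtnet] warning: min_studies={config.min_studies} exceeds the "
            f"{len(signatures)} usable studies; consensus will be empty",
            file=sys.stderr,
        )
    meta = intersect_signatures(signatures, "DOWN", config.min_studies)
    (outdir / "consensus.json").write_text(json.dumps({
        "direction": meta.direction,
        "min_studies": meta.min_studies,
        "n_studies": meta.n_studies,
        "consensus": sorted(meta.consensus),
        "pairwise_overlap": meta.pairwise_overlap.values.tolist(),
        "overall_overlap": meta.overall_overlap,
        "failures": failures,
    }, indent=2))
    report.results["signatures"] = signatures
    report.results["meta"] = meta
    _log("consensus", t0)

    # correlation ranking on the first study containing the whole family
    for m in studies:
        if set(config.family) <= set(m.feature_ids):
            corr = family_correlation_rank(m, config.family)
            corr.table.to_csv(outdir / "family_correlation.tsv", sep="\t")
            report.results["correlation"] = corr
            break
    _log("correlation ranking", t0)

    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return report
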