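"""End-to-end analysis pipeline with a reproducibility manifest.

Stages: read (or synthesise) the connectome -> renormalise FLNe to LNe ->
degree/strength tables and distribution fits -> map-equation modules (+
Louvain comparison) -> hub cartography -> top-flow link ranking -> temporal
traces around the top hubs.  Every stage writes plain CSV/JSON artifacts;
a manifest records input checksums, seeds and parameters so that an
identical configuration reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from . import __version__
from .community import (
    Partition,
    louvain_partition,
    modularity,
    optimize_partition,
    stationary_flow,
    top_flow_links,
)
from .connectome import Connectome, flne_to_lne
from .io import (
    read_adjacency,
    read_injection_records,
    read_link_list,
    write_adjacency,
)
from .roles import assign_roles, extract_hubs_and_connectors, roles_frame
from .stats import compare_families, degree, weight_distance_fit
from .synthetic import SynthConfig, censor, generate
from .tracing import TraceConfig, export_viz, trace

__all__ = ["RunConfig", "run_pipeline", "compare_partitions"]

ALL_STAGES = ("stats", "modules", "roles", "flow", "trace")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be given: either file paths (link list or
    adjacency, optional metadata/records) or a synthetic-generator config.
    """

    link_list: str | None = None
    adjacency: str | None = None
    node_meta: str | None = None
    injection_records: str | None = None
    weight_kind: str = "LNe"
    synth: SynthConfig | None = None
    teleport: float = 0.15
    n_trials: int = 100
    seed: int | None = None
    top_flow_fraction: float = 0.15
    trace: TraceConfig | None = None
    n_trace_seeds: int = 4
    stages: tuple[str, ...] = ALL_STAGES
    outdir: str = "cortexflow_out"

    def __post_init__(self) -> None:
        n_file = sum(x is not None for x in (self.link_list, self.adjacency))
        if (n_file > 0) == (self.synth is not None):
            raise ValueError("exactly one input source: files or a synth config")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_input(cfg: RunConfig) -> tuple[Connectome, dict]:
    prov: dict = {"inputs": {}}
    if cfg.synth is not None:
        c, gt = generate(cfg.synth)
        c = censor(c, gt.measured_set)
        prov["inputs"]["synth"] = asdict(cfg.synth)
        prov["ground_truth_modules"] = gt.partition
        return c, prov
    if cfg.link_list is not None:
        c = read_link_list(cfg.link_list, node_meta=cfg.node_meta, weight_kind=cfg.weight_kind)
        prov["inputs"]["link_list"] = _sha256(cfg.link_list)
    else:
        c = read_adjacency(cfg.adjacency, weight_kind=cfg.weight_kind)
        prov["inputs"]["adjacency"] = _sha256(cfg.adjacency)
    if cfg.node_meta is not None:
        prov["inputs"]["node_meta"] = _sha256(cfg.node_meta)
    if cfg.weight_kind == "FLNe":
        if cfg.injection_records is None:
            raise ValueError("FLNe input requires injection records for renormalisation")
        records = read_injection_records(cfg.injection_records)
        prov["inputs"]["injection_records"] = _sha256(cfg.injection_records)
        c = flne_to_lne(c, records)
    return c, prov


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages and write the artifact bundle.

    Returns a dict of in-memory results; files land under ``cfg.outdir``.
    Identical config + seed yields identical numeric outputs.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    out: dict = {}
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "teleport": cfg.teleport,
        "n_trials": cfg.n_trials,
        "stages": list(cfg.stages),
        "artifacts": [],
    }

    def _emit(name: str) -> str:
        path = os.path.join(cfg.outdir, name)
        manifest["artifacts"].append(name)
        return path

    def _stage(name):
        return name in cfg.stages

    try:
        c, prov = _load_input(cfg)
    except Exception as e:
        raise RuntimeError(f"stage 'read' failed: {e}") from e
    manifest.update(prov)
    out["connectome"] = c
    write_adjacency(c, _emit("lne_adjacency.csv"))

    if _stage("stats"):
        try:
            deg_df = pd.DataFrame({"label": c.labels})
            for direction in ("in", "out"):
                for weighted in (False, True):
                    col = f"{'strength' if weighted else 'k'}_{direction}"
                    deg_df[col] = degree(c, direction, weighted).values
            deg_df.to_csv(_emit("degrees.csv"), index=False)
            fits: dict = {}
            for direction in ("in", "out"):
                ranked = compare_families(degree(c, direction, weighted=False).values)
                fits[f"k_{direction}"] = [
                    {"family": f.family, "log_likelihood": f.log_likelihood, **f.params}
                    for f in ranked
                ]
            if c.D is not None:
                for model in ("exponential", "powerlaw"):
                    fit = weight_distance_fit(c, model)
                    fits[f"decay_{model}"] = {
                        "decay_length_mm": fit.decay_length_mm,
                        "exponent": fit.exponent,
                        "r_squared": fit.r_squared,
                        "n_links": fit.n_links,
                    }
            with open(_emit("fits.json"), "w") as fh:
                json.dump(fits, fh, indent=1)
            out["fits"] = fits
        except Exception as e:
            raise RuntimeError(f"stage 'stats' failed: {e}") from e

    partition: Partition | None = None
    if _stage("modules"):
        try:
            partition = optimize_partition(
                c, teleport=cfg.teleport, n_trials=cfg.n_trials, seed=cfg.seed
            )
            partition.modularity = modularity(c, partition, "undirected")
            lv = louvain_partition(c, seed=cfg.seed)
            partition.to_frame().to_csv(_emit("partition.csv"), index=False)
            summary = {
                "codelength_bits": partition.codelength,
                "modularity_q": partition.modularity,
                "n_modules": partition.n_modules,
                "orphans": partition.orphans,
                "louvain": {
                    "n_modules": lv.n_modules,
                    "modularity_q": lv.modularity,
                    "degenerate": lv.degenerate,
                    "agreement_nmi": compare_partitions(partition, lv)["nmi"],
                },
                "modules": [],
            }
            flow_by_label = dict(zip(partition.labels, partition.node_flow))
            for m in range(partition.n_modules):
                members = partition.members(m)
                members = sorted(members, key=lambda l: -flow_by_label[l])
                summary["modules"].append(
                    {
                        "module": m + 1,
                        "flow": float(partition.module_flow[m]),
                        "n_areas": len(members),
                        "key_areas": members[:6],
                    }
                )
            with open(_emit("modules.json"), "w") as fh:
                json.dump(summary, fh, indent=1)
            out["partition"] = partition
            out["louvain"] = lv
            out["module_summary"] = summary
        except Exception as e:
            raise RuntimeError(f"stage 'modules' failed: {e}") from e

    roles_in = roles_out = None
    if _stage("roles"):
        if partition is None:
            raise RuntimeError("stage 'roles' failed: requires the 'modules' stage")
        try:
            roles_in = assign_roles(c, partition, "in")
            roles_out = assign_roles(c, partition, "out")
            rf = roles_frame(roles_in + roles_out)
            rf.to_csv(_emit("roles.csv"), index=False)
            ranked = extract_hubs_and_connectors(roles_in, roles_out)
            with open(_emit("hubs.json"), "w") as fh:
                json.dump(
                    {k: v.to_dict(orient="records") for k, v in ranked.items()},
                    fh,
                    indent=1,
                )
            out["roles"] = rf
            out["hubs"] = ranked
        except Exception as e:
            raise RuntimeError(f"stage 'roles' failed: {e}") from e

    if _stage("flow"):
        try:
            flow = stationary_flow(c, teleport=cfg.teleport)
            top = top_flow_links(flow, fraction=cfg.top_flow_fraction)
            top.to_csv(_emit("top_links.csv"), index=False)
            out["flow"] = flow
            out["top_links"] = top
        except Exception as e:
            raise RuntimeError(f"stage 'flow' failed: {e}") from e

    if _stage("trace") and c.D is not None:
        try:
            tcfg = cfg.trace or TraceConfig()
            seeds = tuple(tcfg.seeds)
            if not seeds and out.get("hubs") is not None:
                hubs = out["hubs"]["hubs"]
                seeds = tuple(dict.fromkeys(hubs["label"]))[: cfg.n_trace_seeds]
            if not seeds:  # fall back: highest-strength nodes
                s = degree(c, "out", weighted=True).values
                seeds = tuple(np.array(c.labels)[np.argsort(-s)][: cfg.n_trace_seeds])
            tcfg = TraceConfig(
                seeds=seeds,
                velocity=tcfg.velocity,
                synaptic_delay_ms=tcfg.synaptic_delay_ms,
                max_order=tcfg.max_order,
                min_weight=tcfg.min_weight,
                max_length_mm=tcfg.max_length_mm,
                direction=tcfg.direction,
            )
            tr = trace(c, tcfg)
            tr.to_frame().to_csv(_emit("trace_events.csv"), index=False)
            export_viz(c, tr, partition, prefix=os.path.join(cfg.outdir, "viz"))
            manifest["artifacts"] += [
                "viz_nodes.csv",
                "viz_edges.csv",
                "viz_nodes.json",
                "viz_edges.json",
            ]
            out["trace"] = tr
        except Exception as e:
            raise RuntimeError(f"stage 'trace' failed: {e}") from e

    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    out["manifest"] = manifest
    return out


def compare_partitions(p1: Partition, p2: Partition) -> dict[str, float]:
    """Agreement between two partitions of the same node set.

    Normalised mutual information and adjusted Rand index over nodes
    assigned in both partitions (orphans excluded).  By sklearn convention
    NMI of a one-module vs an all-singletons partition is 0.
    """
    if set(p1.labels) != set(p2.labels):
        raise ValueError("partitions cover different node sets")
    lut2 = {lab: m for lab, m in zip(p2.labels, p2.modules)}
    a1, a2 = [], []
    for lab, m in zip(p1.labels, p1.modules):
        m2 = lut2[lab]
        if m >= 0 and m2 >= 0:
            a1.append(m)
            a2.append(m2)
    return {
        "nmi": float(normalized_mutual_info_score(a1, a2)),
        "ari": float(adjusted_rand_score(a1, a2)),
    }
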