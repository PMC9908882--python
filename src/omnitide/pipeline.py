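"""End-to-end orchestration: simulate -> preprocess/DE -> topology ->
classes -> L-R crosstalk -> prizes/network -> controllability.

One global seed is fanned out to per-stage child seeds by stable hashing of
stage names, so single stages are reproducible without bookkeeping. Every
run writes a JSON manifest with file hashes and a parameter echo.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import control, crosstalk, pcsf, synthetic, topology
from .classes import classify_genes
from .preprocess import DEResult, preprocess, select_differential

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    alpha: float = 0.05
    r2_min: float = 0.6
    lfc_min: float = 1.0
    degree: int = 3
    epsilon: float = 0.1
    class_r_high: float = 0.4
    class_r_low: float = -0.4
    p_max: float = 0.01
    c_min: float = 1.0
    pcsf: pcsf.PCSFParams = field(default_factory=pcsf.PCSFParams)
    prize_threshold: float = 1.0
    mode: str = "heuristic"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline on simulated data; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    # 1. simulate
    sim_seed = stage_seed(config.seed, "simulate")
    layers, truth = synthetic.simulate_multiomics(config.simulation, sim_seed)
    edge_df, net_truth = synthetic.simulate_interactome(config.simulation, sim_seed)
    clusters, lr_truth = synthetic.simulate_cluster_expression(
        config.simulation, sim_seed
    )
    synthetic.write_simulation(out / "sim", layers, truth)
    edge_df.to_csv(out / "interactome.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {
        "n_layers": len(layers),
        "n_edges": int(len(edge_df)),
    }

    # 2. preprocess + differential selection per layer
    de: dict[str, DEResult] = {}
    for name, m in sorted(layers.items()):
        mp = preprocess(m, zero_center=config.simulation.batch_sd > 0)
        de[name] = select_differential(
            mp,
            degree=config.degree,
            alpha=config.alpha,
            r2_min=config.r2_min,
            lfc_min=config.lfc_min,
        )
        de[name].to_tsv(out / f"de_{name.lower()}.tsv")
        logger.info(
            "DE %s: %d/%d selected",
            name,
            int(de[name].table["selected"].sum()),
            len(de[name].table),
        )
    manifest["stages"]["de"] = {
        name: int(r.table["selected"].sum()) for name, r in de.items()
    }

    # 3. topology
    configs = {
        name: topology.configuration_matrix(m.values.T.to_numpy(), name)
        for name, m in layers.items()
    }
    rv = topology.rv_matrix(configs)
    rv.to_csv(out / "rv_matrix.tsv", sep="\t")
    skeleton = topology.topology_skeleton(rv, config.epsilon)
    nx.write_graphml(skeleton, out / "topology_skeleton.graphml")
    manifest["stages"]["topology"] = {"n_skeleton_edges": skeleton.number_of_edges()}

    # 4. regulatory classes
    proteomic = [s.name for s in config.simulation.layers if s.proteomic]
    lfc_by_layer = {name: de[name].lfc for name in proteomic if name in de}
    classes = classify_genes(
        lfc_by_layer, r_high=config.class_r_high, r_low=config.class_r_low
    )
    classes.to_csv(out / "classes.tsv", sep="\t", index_label="gene")
    manifest["stages"]["classes"] = classes["class"].value_counts().to_dict()

    # 5. L-R crosstalk
    lr_records = []
    if "SEC" in de and ("MEM" in de or "GLYCO" in de):
        lr_records = crosstalk.find_regulated_lr(
            crosstalk.de_stats(de["SEC"]),
            crosstalk.de_stats(de["MEM"]) if "MEM" in de else pd.DataFrame(),
            truth.lr_db,
            glyco_stats=crosstalk.de_stats(de["GLYCO"]) if "GLYCO" in de else None,
            p_max=config.p_max,
            c_min=config.c_min,
        )
        scores = crosstalk.score_cluster_crosstalk(lr_records, clusters)
        scores.to_csv(out / "lr_scores.tsv", sep="\t", index=False)
    manifest["stages"]["lr"] = {"n_regulated_pairs": len(lr_records)}

    # 6. network: prizes + temporal PCSF
    graph = pcsf.assign_edge_weights(edge_df)
    schedule = synthetic.prize_schedule_from_truth(
        net_truth, graph.nodes, config.simulation.n_timepoints
    )
    schedule.to_csv(out / "prizes.tsv", sep="\t", index_label="node")
    params = pcsf.PCSFParams(
        beta=config.pcsf.beta,
        mu=config.pcsf.mu,
        omega=config.pcsf.omega,
        depth=config.pcsf.depth,
        roots=tuple(net_truth.roots),
    )
    forests, first_seen = pcsf.run_temporal_series(
        graph, schedule, params, mode=config.mode
    )
    growth = pd.DataFrame(
        {
            "first_appearance": first_seen,
        }
    )
    growth.to_csv(out / "network_growth.tsv", sep="\t", index_label="node")
    manifest["stages"]["network"] = {
        t: {"n_nodes": len(f.nodes), "objective": f.objective}
        for t, f in forests.items()
    }

    # 7. controllability on the union of per-timepoint forests
    union = nx.DiGraph()
    for f in forests.values():
        union.add_nodes_from(f.nodes)
        union.add_edges_from(f.edges)
    if union.number_of_nodes() >= 2:
        classification = control.classify_nodes(union)
        classification.to_csv(out / "control.tsv", sep="\t", index_label="node")
        manifest["stages"]["control"] = {
            "n_nodes": union.number_of_nodes(),
            "n_drivers": int(classification.attrs["n_drivers"]),
            "controller_fraction": control.controller_fraction(classification),
        }
    else:
        manifest["stages"]["control"] = {"n_nodes": union.number_of_nodes()}

    for p in sorted(out.rglob("*")):
        if p.is_file():
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
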