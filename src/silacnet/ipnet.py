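"""Bait-normalized SILAC immunoprecipitation networks.

Each IP experiment yields prey H/L enrichments (specific over isotype
control); dividing by the bait's own H/L makes edge weights comparable across
experiments with different IP efficiencies. Reciprocal detections collapse to
one undirected edge carrying the stronger weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd


@dataclass
class IPExperiment:
    bait_id: str
    prey: pd.DataFrame      # columns: protein_id, hl_ratio, ratio_count

    def __post_init__(self) -> None:
        required = {"protein_id", "hl_ratio", "ratio_count"}
        missing = required - set(self.prey.columns)
        if missing:
            raise ValueError(f"prey table missing columns {sorted(missing)}")
        if (self.prey["hl_ratio"] <= 0).any():
            raise ValueError("prey hl_ratio values must be positive")


@dataclass
class InteractionNetwork:
    nodes: pd.DataFrame     # columns: protein_id, module, kWithin
    edges: pd.DataFrame     # columns: source, target, weight, reciprocal


def read_ip_table(path, bait_id: str) -> IPExperiment:
    """Read a per-bait TSV with columns protein_id, hl_ratio, ratio_count."""
    prey = pd.read_csv(path, sep="\t")
    return IPExperiment(bait_id=bait_id, prey=prey)


def normalize_ip(exp: IPExperiment, min_ratio_count: int = 2) -> pd.DataFrame:
    """Bait-normalized edge list from one IP experiment.

    Weight = prey H/L divided by the bait's own H/L; preys quantified with
    fewer than ``min_ratio_count`` peptides are dropped, as is the bait's
    self-edge.
    """
    bait_rows = exp.prey[exp.prey["protein_id"] == exp.bait_id]
    if bait_rows.empty:
        raise ValueError(
            f"bait {exp.bait_id!r} is absent from its own prey table"
        )
    bait_ratio = float(bait_rows["hl_ratio"].iloc[0])
    kept = exp.prey[
        (exp.prey["ratio_count"] >= min_ratio_count)
        & (exp.prey["protein_id"] != exp.bait_id)
    ]
    return pd.DataFrame(
        {
            "source": exp.bait_id,
            "target": kept["protein_id"].to_numpy(),
            "weight": kept["hl_ratio"].to_numpy() / bait_ratio,
        }
    )


def merge_ip_networks(
    experiments: list[IPExperiment],
    connectivity: pd.DataFrame | None = None,
    min_ratio_count: int = 2,
) -> InteractionNetwork:
    """Union of bait-normalized edge lists as one undirected network.

    Reciprocal detections (A pulls B and B pulls A) merge into a single edge
    with weight = max of the two directions and a reciprocal flag. Node
    attributes (module, kWithin) are left-joined from a connectivity table
    when given; proteins absent from it keep NaN attributes.
    """
    if not experiments:
        raise ValueError("at least one IP experiment is required")
    directed: dict[tuple[str, str], float] = {}
    for exp in experiments:
        for edge in normalize_ip(exp, min_ratio_count=min_ratio_count).itertuples():
            directed[(edge.source, edge.target)] = float(edge.weight)
    merged: dict[tuple[str, str], dict] = {}
    for (source, target), weight in directed.items():
        key = tuple(sorted((source, target)))
        reverse = directed.get((target, source))
        record = merged.setdefault(
            key, {"weight": weight, "reciprocal": False}
        )
        record["weight"] = max(record["weight"], weight)
        if reverse is not None:
            record["reciprocal"] = True
    edges = pd.DataFrame(
        [
            {"source": a, "target": b,
             "weight": rec["weight"], "reciprocal": rec["reciprocal"]}
            for (a, b), rec in sorted(merged.items())
        ],
        columns=["source", "target", "weight", "reciprocal"],
    )
    node_ids = sorted(
        set(edges["source"]) | set(edges["target"]) | {e.bait_id for e in experiments}
    )
    nodes = pd.DataFrame({"protein_id": node_ids})
    nodes["module"] = pd.NA
    nodes["kWithin"] = float("nan")
    if connectivity is not None:
        nodes["module"] = nodes["protein_id"].map(connectivity["Module"])
        nodes["kWithin"] = nodes["protein_id"].map(connectivity["kWithin"])
    return InteractionNetwork(nodes=nodes, edges=edges)


def export_network(
    net: InteractionNetwork, path_prefix, format: str = "tsv"
) -> list[str]:
    """Write edge and node tables (TSV) and optionally GraphML.

    ``format`` is ``"tsv"`` or ``"graphml"`` (which writes the TSVs too).
    Returns the written paths.
    """
    edge_path = f"{path_prefix}_edges.tsv"
    node_path = f"{path_prefix}_nodes.tsv"
    net.edges.to_csv(edge_path, sep="\t", index=False)
    net.nodes.to_csv(node_path, sep="\t", index=False)
    written = [edge_path, node_path]
    if format == "graphml":
        graph = nx.Graph()
        for node in net.nodes.itertuples(index=False):
            attrs = {}
            if pd.notna(node.module):
                attrs["module"] = str(node.module)
            if pd.notna(node.kWithin):
                attrs["kWithin"] = float(node.kWithin)
            graph.add_node(node.protein_id, **attrs)
        for edge in net.edges.itertuples(index=False):
            graph.add_edge(
                edge.source, edge.target,
                weight=float(edge.weight), reciprocal=bool(edge.reciprocal),
            )
        graphml_path = f"{path_prefix}.graphml"
        nx.write_graphml(graph, graphml_path)
        written.append(graphml_path)
    elif format != "tsv":
        raise ValueError(f"unknown export format {format!r}")
    return written
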