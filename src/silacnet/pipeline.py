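"""End-to-end orchestration from a single YAML configuration."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import SampleDesign
from .ingest import (
    RatioMatrix,
    read_protein_groups,
    filter_quality,
    to_ratio_matrix,
    filter_missingness,
    impute_zero,
)
from .synthetic import (
    ComplexSpec,
    GeneratorConfig,
    SyntheticDataset,
    generate_dataset,
    make_signature_library,
    write_fixture,
)
from .network import (
    pairwise_correlation,
    signed_adjacency,
    pick_soft_threshold,
    topological_overlap,
    cluster_dendrogram,
    dynamic_tree_cut,
    ModuleAssignment,
)
from .characterize import compute_eigenproteins, intramodular_connectivity
from .stats import (
    replicate_mean_log_enrichment,
    module_enrichment_ttest,
    outlier_zscore,
    adjust_fdr,
)

logger = logging.getLogger(__name__)

_KNOWN_TOP = {"mode", "input_path", "out_dir", "seed", "design", "generator",
              "network", "ingest", "stats"}
_KNOWN_GENERATOR = {"use_library", "n_background", "noise_cv",
                    "background_binding", "detection_midpoint",
                    "detection_slope", "apply_detection", "complexes"}
_KNOWN_NETWORK = {"beta", "candidate_betas", "min_module_size", "cut_fraction",
                  "split_ratio", "static_cut_height"}
_KNOWN_INGEST = {"min_ratio_count", "max_missing"}
_KNOWN_STATS = {"two_sided", "fdr", "leave_one_out"}
_KNOWN_DESIGN = {"conditions", "replicates", "beads_condition"}


def _reject_unknown(section: dict, known: set, name: str) -> None:
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config keys in {name}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    mode: str = "simulate"                  # "simulate" | "table"
    input_path: str | None = None
    out_dir: str = "results"
    seed: int = 0
    design: SampleDesign = field(default_factory=SampleDesign)
    generator: GeneratorConfig | None = None
    beta: int = 15
    candidate_betas: tuple[int, ...] = ()
    min_module_size: int = 5
    cut_fraction: float = 0.99
    split_ratio: float | None = 0.5
    static_cut_height: float | None = None
    min_ratio_count: int = 2
    max_missing: int = 14
    two_sided: bool = False
    leave_one_out: bool = False
    fdr: str = "none"

    def validate(self) -> None:
        if self.mode not in ("simulate", "table"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "table" and not self.input_path:
            raise ValueError("table mode requires input_path")
        if self.mode == "simulate" and self.generator is None:
            raise ValueError("simulate mode requires a generator section")
        if self.max_missing >= self.design.n_samples:
            raise ValueError(
                f"max_missing ({self.max_missing}) must be smaller than the "
                f"number of samples ({self.design.n_samples})"
            )
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")

    def to_dict(self) -> dict:
        generator = None
        if self.generator is not None:
            generator = {
                "n_background": self.generator.n_background,
                "noise_cv": self.generator.noise_cv,
                "background_binding": self.generator.background_binding,
                "detection_midpoint": self.generator.detection_midpoint,
                "detection_slope": self.generator.detection_slope,
                "apply_detection": self.generator.apply_detection,
                "complexes": [
                    {
                        "complex_id": s.complex_id,
                        "member_count": s.member_count,
                        "signature": dict(s.signature),
                        "abundance_scale": s.abundance_scale,
                    }
                    for s in self.generator.complex_specs
                ],
            }
        return {
            "mode": self.mode,
            "input_path": self.input_path,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "design": self.design.to_dict(),
            "generator": generator,
            "network": {
                "beta": self.beta,
                "candidate_betas": list(self.candidate_betas),
                "min_module_size": self.min_module_size,
                "cut_fraction": self.cut_fraction,
                "split_ratio": self.split_ratio,
                "static_cut_height": self.static_cut_height,
            },
            "ingest": {
                "min_ratio_count": self.min_ratio_count,
                "max_missing": self.max_missing,
            },
            "stats": {
                "two_sided": self.two_sided,
                "leave_one_out": self.leave_one_out,
                "fdr": self.fdr,
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        _reject_unknown(payload, _KNOWN_TOP, "config")
        design_raw = payload.get("design", {}) or {}
        _reject_unknown(design_raw, _KNOWN_DESIGN, "design")
        design = SampleDesign.from_dict(design_raw)
        seed = int(payload.get("seed", 0))

        generator = None
        gen_raw = payload.get("generator")
        if gen_raw is not None:
            _reject_unknown(gen_raw, _KNOWN_GENERATOR, "generator")
            complexes_raw = gen_raw.get("complexes")
            if complexes_raw:
                specs = tuple(
                    ComplexSpec(
                        complex_id=c["complex_id"],
                        member_count=int(c["member_count"]),
                        signature={k: float(v) for k, v in c["signature"].items()},
                        abundance_scale=float(c.get("abundance_scale", 1.0)),
                    )
                    for c in complexes_raw
                )
            elif gen_raw.get("use_library", True):
                specs = tuple(make_signature_library(design))
            else:
                specs = ()
            generator = GeneratorConfig(
                complex_specs=specs,
                n_background=int(gen_raw.get("n_background", 300)),
                noise_cv=float(gen_raw.get("noise_cv", 0.2)),
                background_binding=float(gen_raw.get("background_binding", 0.05)),
                detection_midpoint=float(gen_raw.get("detection_midpoint", -3.1)),
                detection_slope=float(gen_raw.get("detection_slope", 2.0)),
                apply_detection=bool(gen_raw.get("apply_detection", True)),
                seed=seed,
            )

        network_raw = payload.get("network", {}) or {}
        _reject_unknown(network_raw, _KNOWN_NETWORK, "network")
        ingest_raw = payload.get("ingest", {}) or {}
        _reject_unknown(ingest_raw, _KNOWN_INGEST, "ingest")
        stats_raw = payload.get("stats", {}) or {}
        _reject_unknown(stats_raw, _KNOWN_STATS, "stats")

        split_ratio = network_raw.get("split_ratio", 0.5)
        config = cls(
            mode=payload.get("mode", "simulate"),
            input_path=payload.get("input_path"),
            out_dir=payload.get("out_dir", "results"),
            seed=seed,
            design=design,
            generator=generator,
            beta=int(network_raw.get("beta", 15)),
            candidate_betas=tuple(network_raw.get("candidate_betas", []) or []),
            min_module_size=int(network_raw.get("min_module_size", 5)),
            cut_fraction=float(network_raw.get("cut_fraction", 0.99)),
            split_ratio=None if split_ratio is None else float(split_ratio),
            static_cut_height=network_raw.get("static_cut_height"),
            min_ratio_count=int(ingest_raw.get("min_ratio_count", 2)),
            max_missing=int(ingest_raw.get("max_missing", 14)),
            two_sided=bool(stats_raw.get("two_sided", False)),
            leave_one_out=bool(stats_raw.get("leave_one_out", False)),
            fdr=stats_raw.get("fdr", "none"),
        )
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        return cls.from_dict(payload)


@dataclass
class ResultsBundle:
    matrix: RatioMatrix                 # filtered, un-imputed
    imputed: RatioMatrix
    assignment: ModuleAssignment
    eigenproteins: object
    connectivity: pd.DataFrame
    module_tests: pd.DataFrame
    outliers: pd.DataFrame
    soft_threshold: pd.DataFrame | None
    manifest: dict
    dataset: SyntheticDataset | None = None


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute ingest -> filter -> impute -> network -> modules -> statistics.

    Writes all output tables plus a JSON manifest into ``config.out_dir``.
    The manifest (config hash, versions, seed, stage counts) is timestamp-free
    so that reruns of a fixed-seed simulate config are bit-identical.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    design = config.design
    counts: dict[str, int] = {}
    dataset = None

    if config.mode == "simulate":
        dataset = generate_dataset(design, config.generator)
        fixture_dir = os.path.join(config.out_dir, "fixture")
        table_path, _ = write_fixture(dataset, fixture_dir)
        logger.info("simulate: wrote fixture with %d proteins", len(dataset.protein_ids))
    else:
        table_path = config.input_path
        if not os.path.exists(table_path):
            raise FileNotFoundError(f"input table not found: {table_path}")

    table = read_protein_groups(table_path, design)
    counts["ingested"] = len(table)
    table = filter_quality(table, min_ratio_count=config.min_ratio_count)
    counts["after_quality_filter"] = len(table)
    matrix = to_ratio_matrix(table)
    matrix = filter_missingness(matrix, max_missing=config.max_missing)
    counts["after_missingness_filter"] = matrix.n_proteins
    imputed = impute_zero(matrix)

    soft_table = None
    if config.candidate_betas:
        soft_table = pick_soft_threshold(imputed, list(config.candidate_betas))
        soft_table.to_csv(
            os.path.join(config.out_dir, "soft_threshold.tsv"), sep="\t", index=False
        )

    cor = pairwise_correlation(imputed)
    counts["network_proteins"] = len(cor.protein_ids)
    adj = signed_adjacency(cor, beta=config.beta)
    tom = topological_overlap(adj)
    dendro = cluster_dendrogram(tom)
    assignment = dynamic_tree_cut(
        dendro,
        tom,
        min_module_size=config.min_module_size,
        cut_fraction=config.cut_fraction,
        split_ratio=config.split_ratio,
        static_cut_height=config.static_cut_height,
    )
    counts["modules"] = len(assignment.module_names())
    counts["grey_proteins"] = int((assignment.labels == "grey").sum())

    # restrict the statistics matrix to networked proteins for consistency
    kept = RatioMatrix(
        values=matrix.values.loc[cor.protein_ids], design=design
    )
    eig = compute_eigenproteins(imputed, assignment)
    connectivity = intramodular_connectivity(adj, assignment)
    d = replicate_mean_log_enrichment(kept)
    module_tests = module_enrichment_ttest(d, assignment)
    outliers = outlier_zscore(
        d, two_sided=config.two_sided, leave_one_out=config.leave_one_out
    )
    if config.fdr != "none":
        module_tests["p_adjusted"] = adjust_fdr(module_tests["p"], config.fdr)
        outliers["p_adjusted"] = adjust_fdr(outliers["p"], config.fdr)

    matrix.to_tsv(os.path.join(config.out_dir, "ratio_matrix.tsv"))
    assignment.to_tsv(os.path.join(config.out_dir, "modules.tsv"))
    eig.to_tsv(os.path.join(config.out_dir, "eigenproteins.tsv"))
    connectivity.to_csv(os.path.join(config.out_dir, "connectivity.tsv"), sep="\t")
    module_tests.to_csv(
        os.path.join(config.out_dir, "module_enrichment.tsv"), sep="\t", index=False
    )
    outliers.to_csv(
        os.path.join(config.out_dir, "outliers.tsv"), sep="\t", index=False
    )
    with open(os.path.join(config.out_dir, "dendrogram.newick"), "w") as handle:
        handle.write(dendro.to_newick() + "\n")

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "silacnet": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": counts,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    for stage, value in counts.items():
        logger.info("stage %s: %d", stage, value)
    return ResultsBundle(
        matrix=matrix,
        imputed=imputed,
        assignment=assignment,
        eigenproteins=eig,
        connectivity=connectivity,
        module_tests=module_tests,
        outliers=outliers,
        soft_threshold=soft_table,
        manifest=manifest,
        dataset=dataset,
    )
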