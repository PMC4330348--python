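"""Module summaries: eigenproteins, intramodular connectivity, hub proteins."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import RatioMatrix
from .network import AdjacencyMatrix, ModuleAssignment, GREY

logger = logging.getLogger(__name__)


@dataclass
class Eigenproteins:
    """First-principal-component summary per non-grey module.

    ``profiles`` is a modules x samples frame of unit-norm eigenprotein
    vectors, sign-oriented to correlate positively with the module's mean
    standardized profile; ``variance_explained`` is the fraction of the
    module's standardized variance captured by the component.
    """

    profiles: pd.DataFrame
    variance_explained: pd.Series

    def to_tsv(self, path) -> None:
        out = self.profiles.copy()
        out.insert(0, "VarianceExplained", self.variance_explained)
        out.rename_axis("Module").to_csv(path, sep="\t")


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    means = values.mean(axis=1, keepdims=True)
    stds = values.std(axis=1, keepdims=True)
    return (values - means) / stds


def compute_eigenproteins(
    matrix: RatioMatrix, assignment: ModuleAssignment
) -> Eigenproteins:
    """Eigenprotein (first right-singular direction over samples) per module.

    Member rows are standardized to mean 0 / variance 1 across samples so
    abundance scale cannot dominate the component. Zero-variance rows are
    excluded with a warning.
    """
    values = matrix.values
    profiles: dict[str, np.ndarray] = {}
    var_explained: dict[str, float] = {}
    for module in assignment.module_names():
        members = [p for p in assignment.members(module) if p in values.index]
        sub = values.loc[members].to_numpy(dtype=float)
        keep = sub.std(axis=1) > 0
        if not keep.all():
            excluded = [m for m, k in zip(members, keep) if not k]
            logger.warning(
                "compute_eigenproteins: excluding %d zero-variance rows from "
                "module %s (%s)", len(excluded), module, ", ".join(excluded[:5]),
            )
            sub = sub[keep]
        if sub.shape[0] == 0:
            continue
        standardized = _standardize_rows(sub)
        _, singular, vt = np.linalg.svd(standardized, full_matrices=False)
        eigen = vt[0]
        total = float((singular ** 2).sum())
        var_explained[module] = float(singular[0] ** 2 / total) if total > 0 else 0.0
        mean_profile = standardized.mean(axis=0)
        if float(eigen @ mean_profile) < 0:
            eigen = -eigen
        profiles[module] = eigen
    frame = pd.DataFrame.from_dict(
        profiles, orient="index", columns=list(values.columns)
    )
    frame = frame.loc[[m for m in assignment.module_names() if m in frame.index]]
    return Eigenproteins(
        profiles=frame,
        variance_explained=pd.Series(var_explained).loc[frame.index],
    )


def intramodular_connectivity(
    adj: AdjacencyMatrix, assignment: ModuleAssignment
) -> pd.DataFrame:
    """Per-protein connectivity table.

    ``kWithin_raw`` sums adjacencies to same-module proteins; ``kWithin``
    divides by the module maximum (so each module's top protein scores exactly
    1); ``kTotal`` sums adjacencies to every protein. Grey proteins carry
    NaN normalized connectivity.
    """
    ids = adj.protein_ids
    labels = assignment.labels.reindex(ids)
    if labels.isna().any():
        missing = labels.index[labels.isna()].tolist()
        raise ValueError(f"assignment lacks labels for {missing[:5]}")
    a = np.asarray(adj.values, dtype=float)
    label_values = labels.to_numpy()
    k_total = a.sum(axis=1)
    k_within_raw = np.zeros(len(ids))
    for module in np.unique(label_values):
        in_module = label_values == module
        k_within_raw[in_module] = a[np.ix_(in_module, in_module)].sum(axis=1)
    table = pd.DataFrame(
        {
            "Module": label_values,
            "kWithin_raw": k_within_raw,
            "kWithin": np.nan,
            "kTotal": k_total,
        },
        index=pd.Index(ids, name="ProteinID"),
    )
    for module in np.unique(label_values):
        if module == GREY:
            continue
        in_module = table["Module"] == module
        peak = table.loc[in_module, "kWithin_raw"].max()
        if peak > 0:
            table.loc[in_module, "kWithin"] = table.loc[in_module, "kWithin_raw"] / peak
    return table


def identify_hubs(connectivity: pd.DataFrame, top_n: int = 1) -> pd.DataFrame:
    """Top proteins per module by normalized kWithin.

    Ties broken by kTotal, then protein id; grey proteins are never hubs.
    Returns a frame with Module, ProteinID, rank and connectivity columns.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    rows = []
    table = connectivity[connectivity["Module"] != GREY]
    for module, sub in table.groupby("Module", sort=False):
        ordered = (
            sub.reset_index()
            .sort_values(by=["kWithin", "kTotal", "ProteinID"],
                         ascending=[False, False, True])
            .head(top_n)
        )
        for rank, record in enumerate(ordered.itertuples(index=False), start=1):
            rows.append(
                {
                    "Module": module,
                    "ProteinID": record.ProteinID,
                    "rank": rank,
                    "kWithin": record.kWithin,
                    "kWithin_raw": record.kWithin_raw,
                    "kTotal": record.kTotal,
                }
            )
    return pd.DataFrame(rows, columns=["Module", "ProteinID", "rank", "kWithin",
                                       "kWithin_raw", "kTotal"])
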