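"""Reading and filtering of protein-groups ratio tables.

The input dialect is a tab-separated table with one row per protein group:
``ProteinID``, ``GeneName``, ``Contaminant`` (+/-), ``Reverse`` (+/-), then one
``Ratio H/L <sample>`` and one ``Ratio H/L count <sample>`` column per sample
in the design. Empty ratio cells are missing; parsed zeros are treated as
missing as well, because true H/L ratios are strictly positive — zeros appear
only after explicit imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import SampleDesign

logger = logging.getLogger(__name__)

RATIO_PREFIX = "Ratio H/L "
COUNT_PREFIX = "Ratio H/L count "
META_COLUMNS = ("ProteinID", "GeneName", "Contaminant", "Reverse")


def ratio_column(sample: str) -> str:
    return RATIO_PREFIX + sample

def count_column(sample: str) -> str:
    return COUNT_PREFIX + sample


@dataclass
class ProteinGroupsTable:
    """Parsed protein-groups table: metadata, ratios and ratio counts.

    ``ratios`` and ``counts`` are protein x sample frames indexed by
    ``ProteinID`` with columns in design sample order; missing ratios are NaN.
    """

    meta: pd.DataFrame      # index ProteinID; columns GeneName, Contaminant, Reverse
    ratios: pd.DataFrame    # index ProteinID; columns design.sample_names
    counts: pd.DataFrame    # same shape as ratios, integer ratio counts
    design: SampleDesign

    @property
    def protein_ids(self) -> list[str]:
        return list(self.ratios.index)

    def __len__(self) -> int:
        return len(self.ratios)


@dataclass
class RatioMatrix:
    """Protein x sample H/L ratio matrix with explicit missingness.

    Before imputation, missing entries are NaN and ``mask`` is None. After
    :func:`impute_zero`, missing entries are 0 and ``mask`` records which
    entries were genuinely observed (True = observed), so downstream
    statistics can still ignore imputed values.
    """

    values: pd.DataFrame
    design: SampleDesign
    mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        expected = self.design.sample_names
        if list(self.values.columns) != expected:
            raise ValueError(
                "sample columns do not match the design "
                f"(expected {expected}, got {list(self.values.columns)})"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return len(self.values)

    @property
    def is_imputed(self) -> bool:
        return self.mask is not None

    def present_mask(self) -> pd.DataFrame:
        """Boolean frame, True where a value was genuinely measured."""
        if self.mask is not None:
            return self.mask
        return self.values.notna()

    def n_missing(self) -> pd.Series:
        return (~self.present_mask()).sum(axis=1)

    def copy(self) -> "RatioMatrix":
        return RatioMatrix(
            values=self.values.copy(),
            design=self.design,
            mask=None if self.mask is None else self.mask.copy(),
        )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="ProteinID")

    @classmethod
    def from_tsv(cls, path, design: SampleDesign) -> "RatioMatrix":
        values = pd.read_csv(path, sep="\t", index_col="ProteinID",
                             float_precision="round_trip")
        return cls(values=values[design.sample_names], design=design)


def _parse_flag(series: pd.Series) -> pd.Series:
    return series.fillna("").astype(str).str.strip().eq("+")


def read_protein_groups(path, design: SampleDesign) -> ProteinGroupsTable:
    """Parse a tab-separated protein-groups table against a sample design.

    Raises ``ValueError`` naming the first absent required column, and on
    duplicated protein identifiers.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"ProteinID": str, "GeneName": str},
                      float_precision="round_trip")
    for column in META_COLUMNS:
        if column not in raw.columns:
            raise ValueError(f"protein-groups table is missing column {column!r}")
    for sample in design.sample_names:
        for column in (ratio_column(sample), count_column(sample)):
            if column not in raw.columns:
                raise ValueError(f"protein-groups table is missing column {column!r}")
    if raw["ProteinID"].duplicated().any():
        dupes = raw.loc[raw["ProteinID"].duplicated(), "ProteinID"].tolist()
        raise ValueError(f"duplicate protein ids: {dupes[:5]}")

    raw = raw.set_index("ProteinID")
    meta = pd.DataFrame(
        {
            "GeneName": raw["GeneName"],
            "Contaminant": _parse_flag(raw["Contaminant"]),
            "Reverse": _parse_flag(raw["Reverse"]),
        }
    )
    ratios = raw[[ratio_column(s) for s in design.sample_names]].apply(
        pd.to_numeric, errors="coerce"
    )
    ratios.columns = design.sample_names
    # strictly positive measurements: parsed zeros / negatives are missing
    ratios = ratios.where(ratios > 0)
    counts = (
        raw[[count_column(s) for s in design.sample_names]]
        .apply(pd.to_numeric, errors="coerce")
        .fillna(0)
        .astype(int)
    )
    counts.columns = design.sample_names
    logger.info("read_protein_groups: %d proteins from %s", len(ratios), path)
    return ProteinGroupsTable(meta=meta, ratios=ratios, counts=counts, design=design)


def filter_quality(
    table: ProteinGroupsTable, min_ratio_count: int = 2
) -> ProteinGroupsTable:
    """Drop contaminant/decoy rows and mask under-quantified ratios.

    Ratios backed by fewer than ``min_ratio_count`` redundant peptides are set
    missing; rows left with no present ratio are removed.
    """
    keep_rows = ~(table.meta["Contaminant"] | table.meta["Reverse"])
    meta = table.meta.loc[keep_rows]
    ratios = table.ratios.loc[keep_rows].where(
        table.counts.loc[keep_rows] >= min_ratio_count
    )
    counts = table.counts.loc[keep_rows]
    nonempty = ratios.notna().any(axis=1)
    dropped = len(table) - int(nonempty.sum())
    logger.info(
        "filter_quality: %d proteins in, %d out (%d dropped)",
        len(table), int(nonempty.sum()), dropped,
    )
    return ProteinGroupsTable(
        meta=meta.loc[nonempty],
        ratios=ratios.loc[nonempty],
        counts=counts.loc[nonempty],
        design=table.design,
    )


def to_ratio_matrix(table: ProteinGroupsTable) -> RatioMatrix:
    return RatioMatrix(values=table.ratios.copy(), design=table.design)


def filter_missingness(matrix: RatioMatrix, max_missing: int = 14) -> RatioMatrix:
    """Retain proteins with at most ``max_missing`` missing entries.

    Equivalently, a protein must be quantified in at least
    ``n_samples - max_missing`` samples (4 of 18 under the defaults).
    """
    total = matrix.design.n_samples
    if max_missing >= total:
        raise ValueError(
            f"max_missing ({max_missing}) must be smaller than the number of "
            f"samples ({total})"
        )
    if matrix.is_imputed:
        raise ValueError("filter_missingness expects an un-imputed matrix")
    n_missing = matrix.values.isna().sum(axis=1)
    keep = n_missing <= max_missing
    logger.info(
        "filter_missingness: %d proteins in, %d out (%d dropped)",
        matrix.n_proteins, int(keep.sum()), int((~keep).sum()),
    )
    return RatioMatrix(values=matrix.values.loc[keep].copy(), design=matrix.design)


def impute_zero(matrix: RatioMatrix) -> RatioMatrix:
    """Replace missing entries by zero, retaining the observation mask."""
    if matrix.is_imputed:
        return matrix.copy()
    mask = matrix.values.notna()
    return RatioMatrix(
        values=matrix.values.fillna(0.0), design=matrix.design, mask=mask
    )
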