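"""Enrichment statistics: module-vs-beads paired t-tests and outlier z-scores.

Inputs are replicate-mean, log2-transformed H/L ratios with the beads-only
value subtracted per protein (the quantity called ``d`` throughout). Replicate
means ignore missing values, which is why the un-imputed matrix (or the
imputation mask) is required here.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ingest import RatioMatrix
from .network import ModuleAssignment, GREY

logger = logging.getLogger(__name__)


def replicate_mean_log_enrichment(matrix: RatioMatrix) -> pd.DataFrame:
    """Beads-subtracted log2 replicate-mean ratios, proteins x specific conditions.

    Per protein and condition: mean over present replicates (missing if none),
    log2, minus the protein's beads-only log2 mean. Proteins without a beads
    mean get NaN across the board. Raises on nonpositive means, which cannot
    arise from true ratios (pass the un-imputed matrix, not the zero-filled
    one).
    """
    design = matrix.design
    present = matrix.present_mask()
    values = matrix.values.where(present)
    means = pd.DataFrame(index=values.index, columns=list(design.conditions),
                         dtype=float)
    for condition in design.conditions:
        means[condition] = values[design.samples_of(condition)].mean(axis=1)
    if (means.to_numpy() <= 0).any():
        raise ValueError(
            "nonpositive replicate-mean ratio; true H/L ratios are strictly "
            "positive — was the matrix zero-imputed without a mask?"
        )
    log_means = np.log2(means)
    beads = log_means[design.beads_condition]
    d = log_means[list(design.specific_conditions)].sub(beads, axis=0)
    return d


def module_enrichment_ttest(
    d: pd.DataFrame, assignment: ModuleAssignment, include_grey: bool = False
) -> pd.DataFrame:
    """Paired two-tailed t-test of module binding versus beads, per condition.

    The per-protein differences (specific minus beads, log2 scale) are exactly
    the columns of ``d``; for each (module, condition) the classic paired t is
    t = mean / (sd / sqrt(n)) with df = n - 1. Degenerate cases are flagged:
    fewer than 2 pairs, or zero variance.
    """
    modules = assignment.module_names(include_grey=include_grey)
    rows = []
    for module in modules:
        members = [p for p in assignment.members(module) if p in d.index]
        sub = d.loc[members]
        for condition in d.columns:
            diffs = sub[condition].dropna().to_numpy(dtype=float)
            n = diffs.size
            record = {
                "Module": module,
                "Condition": condition,
                "n_pairs": n,
                "t": np.nan,
                "df": np.nan,
                "p": np.nan,
                "flag": "",
            }
            if n < 2:
                record["flag"] = "insufficient_pairs"
            else:
                mean = diffs.mean()
                sd = diffs.std(ddof=1)
                if sd == 0:
                    if mean == 0:
                        record.update(t=0.0, df=n - 1, p=1.0, flag="degenerate_variance")
                    else:
                        record.update(
                            t=np.inf if mean > 0 else -np.inf,
                            df=n - 1, p=0.0, flag="degenerate_variance",
                        )
                else:
                    t = mean / (sd / np.sqrt(n))
                    record.update(
                        t=t, df=n - 1, p=2.0 * sps.t.sf(abs(t), df=n - 1)
                    )
            rows.append(record)
    return pd.DataFrame(rows)


def outlier_zscore(
    d: pd.DataFrame,
    two_sided: bool = False,
    leave_one_out: bool = False,
    min_proteins: int = 3,
) -> pd.DataFrame:
    """Per-protein outlier z-scores against a no-enrichment null.

    Within each condition the spread sigma is the sample standard deviation
    of all defined ``d`` values; z_i = d_i / sigma with the null mean pinned
    at zero (standard deviations above zero). p is the upper-tail normal
    probability, or two-tailed if requested. ``leave_one_out`` recomputes
    sigma excluding the scored protein. Returns a long frame with flags for
    degenerate conditions.
    """
    rows = []
    for condition in d.columns:
        col = d[condition]
        defined = col.dropna()
        values = defined.to_numpy(dtype=float)
        if values.size < min_proteins:
            flag = "insufficient_proteins"
            sigma = np.nan
        else:
            sigma = values.std(ddof=1)
            flag = "degenerate_sigma" if sigma == 0 else ""
        for pid, value in defined.items():
            if flag:
                z = p = np.nan
            else:
                if leave_one_out:
                    others = values[defined.index != pid]
                    s = others.std(ddof=1) if others.size >= 2 else np.nan
                else:
                    s = sigma
                z = value / s
                p = 2.0 * sps.norm.sf(abs(z)) if two_sided else sps.norm.sf(z)
            rows.append(
                {"ProteinID": pid, "Condition": condition, "d": value,
                 "z": z, "p": p, "flag": flag}
            )
    return pd.DataFrame(
        rows, columns=["ProteinID", "Condition", "d", "z", "p", "flag"]
    )


def adjust_fdr(p_values, method: str = "none") -> np.ndarray:
    """Optionally Benjamini-Hochberg adjust a vector of p-values.

    ``method="none"`` is the identity (the faithful default: raw p-values are
    reported); ``"benjamini_hochberg"`` applies the step-up procedure over the
    non-NaN entries.
    """
    p = np.asarray(p_values, dtype=float)
    if method == "none":
        return p.copy()
    if method in ("benjamini_hochberg", "bh", "fdr_bh"):
        from statsmodels.stats.multitest import multipletests

        adjusted = np.full_like(p, np.nan)
        defined = np.isfinite(p)
        if defined.any():
            adjusted[defined] = multipletests(p[defined], method="fdr_bh")[1]
        return adjusted
    raise ValueError(f"unknown FDR method {method!r}")
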