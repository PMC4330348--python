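"""Synthetic SILAC peptide-capture datasets with planted ground truth.

A forward model of the mixed-reference capture assay: complexes bind as
units with a condition-specific affinity signature, heavy and light pulldowns
receive independent multiplicative lognormal noise, the light eluates are
pooled per replicate into a common reference, and detection of each H/L ratio
follows a logistic model on the log bound amount (so low-abundance captures
go missing preferentially).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import SampleDesign
from .ingest import RatioMatrix, ratio_column, count_column

BACKGROUND_LABEL = "background"


@dataclass(frozen=True)
class ComplexSpec:
    """A planted protein complex with a per-condition binding signature."""

    complex_id: str
    member_count: int
    signature: dict[str, float]     # condition -> nonnegative affinity
    abundance_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")
        if self.abundance_scale <= 0:
            raise ValueError("abundance_scale must be positive")
        if any(v < 0 for v in self.signature.values()):
            raise ValueError(f"negative signature entry in {self.complex_id!r}")
        if not any(v > 0 for v in self.signature.values()):
            raise ValueError(f"all-zero signature in {self.complex_id!r}")

    def signature_vector(self, design: SampleDesign) -> np.ndarray:
        missing = set(self.signature) - set(design.conditions)
        if missing:
            raise ValueError(
                f"signature of {self.complex_id!r} names unknown conditions {sorted(missing)}"
            )
        return np.array(
            [self.signature.get(c, 0.0) for c in design.conditions], dtype=float
        )


@dataclass(frozen=True)
class GeneratorConfig:
    complex_specs: tuple[ComplexSpec, ...]
    n_background: int = 300
    noise_cv: float = 0.2
    background_binding: float = 0.05
    detection_midpoint: float = -3.1
    detection_slope: float = 2.0
    apply_detection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "complex_specs", tuple(self.complex_specs))
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.detection_slope < 0:
            raise ValueError("detection_slope must be >= 0")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated ratios plus the planted truth used to produce them."""

    ratios: RatioMatrix
    truth_labels: pd.Series                 # protein_id -> complex_id or "background"
    truth_signatures: tuple[ComplexSpec, ...]
    bound_heavy: np.ndarray                 # protein x condition x replicate
    counts: pd.DataFrame                    # simulated ratio counts, protein x sample

    @property
    def protein_ids(self) -> list[str]:
        return self.ratios.protein_ids


def make_signature_library(design: SampleDesign | None = None) -> list[ComplexSpec]:
    """Archetype complex signatures spanning the main reader-behaviour classes.

    Classes: an HP1-like K9me3 reader abolished by the adjacent phospho mark,
    an Atrx-like methyl reader indifferent to it, a 14-3-3-like S28ph reader,
    a deacetylase-like unmodified-tail binder displaced by any mark, a
    remodeller-like binder displaced by phosphorylation only, a PRC2-like
    K27me3 reader with 3x stronger K9me3 binding, plus two broad binders.
    """
    design = design or SampleDesign()
    b = design.beads_condition
    specs = [
        # K9me3 reader abolished by the adjacent phospho switch
        ComplexSpec("hp1_like", 40, {
            "H3_1-20_unmod": 0.2, "H3K9me3": 10.0, "H3S10ph": 0.1,
            "H3K9me3S10ph": 0.6, "H3_18-38_unmod": 0.1, "H3K27me3": 0.8,
            "H3S28ph": 0.1, "H3K27me3S28ph": 0.1, b: 0.1,
        }),
        # methyl reader indifferent to the phospho switch (within 20%)
        ComplexSpec("atrx_like", 12, {
            "H3_1-20_unmod": 0.1, "H3K9me3": 6.0, "H3S10ph": 0.05,
            "H3K9me3S10ph": 6.5, "H3K27me3": 0.3, b: 0.1,
        }),
        # S28ph reader
        ComplexSpec("p1433_like", 7, {
            "H3S10ph": 1.5, "H3S28ph": 10.0, "H3K27me3S28ph": 7.0, b: 0.1,
        }),
        # unmodified-tail binder, reduced by K9me3 or S10ph, lowest on both
        ComplexSpec("hdac_like", 30, {
            "H3_1-20_unmod": 10.0, "H3K9me3": 3.5, "H3S10ph": 4.0,
            "H3K9me3S10ph": 1.0, "H3_18-38_unmod": 6.0, "H3K27me3": 0.3,
            "H3S28ph": 0.2, b: 0.2,
        }),
        # unmod = K9me3 binder displaced by phosphorylation
        ComplexSpec("remodeller_like", 25, {
            "H3_1-20_unmod": 6.0, "H3K9me3": 6.0, "H3S10ph": 0.6,
            "H3K9me3S10ph": 0.8, "H3_18-38_unmod": 1.0, "H3K27me3": 0.2, b: 0.2,
        }),
        # K27me3 reader with exactly 3x stronger K9me3 binding
        ComplexSpec("prc2_like", 10, {
            "H3_1-20_unmod": 0.3, "H3K9me3": 4.5, "H3S10ph": 0.1,
            "H3K9me3S10ph": 0.2, "H3_18-38_unmod": 8.0, "H3K27me3": 1.5,
            "H3K27me3S28ph": 1.2, b: 0.1,
        }),
        # S10ph reader
        ComplexSpec("s10ph_like", 5, {
            "H3_1-20_unmod": 0.5, "H3K9me3": 0.2, "H3S10ph": 9.0,
            "H3K9me3S10ph": 2.0, "H3_18-38_unmod": 0.3, "H3S28ph": 1.0,
            "H3K27me3S28ph": 0.2, b: 0.1,
        }),
        # abundant nonspecific bead binder
        ComplexSpec("nonspec_like", 60, {
            c: 1.0 for c in design.conditions if c != b
        } | {b: 6.0}, abundance_scale=2.0),
    ]
    return specs


def _protein_labels(config: GeneratorConfig) -> list[tuple[str, str]]:
    """(protein_id, truth_label) pairs, complexes first then background."""
    rows: list[tuple[str, str]] = []
    for spec in config.complex_specs:
        for k in range(1, spec.member_count + 1):
            rows.append((f"{spec.complex_id}_{k:03d}", spec.complex_id))
    for k in range(1, config.n_background + 1):
        rows.append((f"bg_{k:04d}", BACKGROUND_LABEL))
    return rows


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=sigma, size=shape)


def simulate_binding(
    specs: tuple[ComplexSpec, ...] | list[ComplexSpec],
    design: SampleDesign,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bound-amount tensor (protein x condition x replicate).

    Every member of a complex shares the complex signature (the complex binds
    as a unit); background proteins have a flat signature equal to
    ``background_binding``. Noise is multiplicative lognormal with unit mean
    and coefficient of variation ``noise_cv``, drawn independently per
    (protein, condition, replicate).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = _protein_labels(config)
    n_cond, n_rep = design.n_conditions, design.replicates
    expected = np.empty((len(rows), n_cond), dtype=float)
    sig_by_id = {
        s.complex_id: s.abundance_scale
        * (s.signature_vector(design) + config.background_binding)
        for s in config.complex_specs
    }
    flat = np.full(n_cond, config.background_binding, dtype=float)
    for i, (_, label) in enumerate(rows):
        expected[i] = sig_by_id.get(label, flat)
    bound = expected[:, :, None] * np.ones((1, 1, n_rep))
    bound = bound * _lognormal_noise(rng, config.noise_cv, bound.shape)
    return bound


def apply_mixed_reference(
    heavy: np.ndarray, light: np.ndarray, design: SampleDesign
) -> RatioMatrix:
    """Pool each replicate's light eluates into a common reference and ratio.

    For protein i and replicate r the reference is the mean of that protein's
    light amounts over all conditions; H/L(i, c, r) = heavy(i, c, r) divided
    by the reference, missing where the reference is zero. With heavy = light
    and no noise, each protein's ratios sum to the number of conditions.
    """
    if heavy.shape != light.shape:
        raise ValueError(f"shape mismatch: heavy {heavy.shape} vs light {light.shape}")
    n_prot, n_cond, n_rep = heavy.shape
    if n_cond != design.n_conditions or n_rep != design.replicates:
        raise ValueError("tensor dimensions do not match the design")
    reference = light.mean(axis=1)                      # protein x replicate
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = heavy / reference[:, None, :]
    ratios[~np.isfinite(ratios)] = np.nan
    flat = ratios.reshape(n_prot, n_cond * n_rep)       # condition-major
    protein_ids = [pid for pid, _ in _dummy_ids(n_prot)]
    values = pd.DataFrame(flat, index=protein_ids, columns=design.sample_names)
    return RatioMatrix(values=values, design=design)


def _dummy_ids(n: int) -> list[tuple[str, str]]:
    return [(f"p{i:05d}", "") for i in range(n)]


def apply_missingness(
    ratios: RatioMatrix,
    bound: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> RatioMatrix:
    """Drop entries stochastically under a logistic detection model.

    Retention probability is logistic(detection_slope x (log bound amount -
    detection_midpoint)); a slope of zero gives probability one half
    everywhere, and already-missing entries stay missing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_prot = ratios.n_proteins
    n_cond, n_rep = ratios.design.n_conditions, ratios.design.replicates
    if bound.shape != (n_prot, n_cond, n_rep):
        raise ValueError("bound tensor dimensions do not match the ratio matrix")
    flat_bound = bound.reshape(n_prot, n_cond * n_rep)
    if config.detection_slope == 0:
        p_detect = np.full(flat_bound.shape, 0.5)
    else:
        with np.errstate(divide="ignore"):
            log_bound = np.where(flat_bound > 0, np.log(flat_bound), -np.inf)
        p_detect = expit(config.detection_slope * (log_bound - config.detection_midpoint))
    detected = rng.random(flat_bound.shape) < p_detect
    values = ratios.values.where(pd.DataFrame(
        detected, index=ratios.values.index, columns=ratios.values.columns
    ))
    return RatioMatrix(values=values, design=ratios.design)


def generate_dataset(
    design: SampleDesign, config: GeneratorConfig
) -> SyntheticDataset:
    """Full forward simulation: binding, mixed reference, detection, counts.

    All randomness flows from ``config.seed``, so a fixed seed reproduces the
    dataset bit-identically.
    """
    rng = np.random.default_rng(config.seed)
    rows = _protein_labels(config)
    heavy = simulate_binding(config.complex_specs, design, config, rng)
    light = simulate_binding(config.complex_specs, design, config, rng)
    matrix = apply_mixed_reference(heavy, light, design)
    protein_ids = [pid for pid, _ in rows]
    matrix = RatioMatrix(
        values=matrix.values.set_axis(protein_ids, axis=0), design=design
    )
    if config.apply_detection:
        matrix = apply_missingness(matrix, heavy, config, rng)
    # ratio counts stand in for redundant quantified peptides: >= 2 where
    # detected so that default quality filtering keeps synthetic entries
    counts = np.where(
        matrix.values.notna(), 2 + rng.poisson(3.0, size=matrix.values.shape), 0
    )
    counts = pd.DataFrame(counts, index=protein_ids, columns=design.sample_names)
    labels = pd.Series(dict(rows), name="ComplexID").loc[protein_ids]
    return SyntheticDataset(
        ratios=matrix,
        truth_labels=labels,
        truth_signatures=tuple(config.complex_specs),
        bound_heavy=heavy,
        counts=counts,
    )


def write_fixture(
    dataset: SyntheticDataset,
    path,
    spike_contaminants: int = 0,
    spike_decoys: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[str, str]:
    """Write a protein-groups-style TSV plus a truth-labels TSV.

    Optionally spikes extra contaminant / decoy-flagged rows (with valid-looking
    ratios) to exercise quality filtering. Returns the two file paths.
    """
    import os

    os.makedirs(path, exist_ok=True)
    design = dataset.ratios.design
    if rng is None:
        rng = np.random.default_rng(12345)

    records = []
    for pid in dataset.protein_ids:
        rec = {
            "ProteinID": pid,
            "GeneName": pid.upper(),
            "Contaminant": "-",
            "Reverse": "-",
        }
        for sample in design.sample_names:
            value = dataset.ratios.values.at[pid, sample]
            rec[ratio_column(sample)] = "" if pd.isna(value) else repr(float(value))
            rec[count_column(sample)] = int(dataset.counts.at[pid, sample])
        records.append(rec)

    def _spiked(idx: int, flag: str) -> dict:
        rec = {
            "ProteinID": f"{flag.lower()}_{idx:03d}",
            "GeneName": f"{flag.upper()}{idx}",
            "Contaminant": "+" if flag == "con" else "-",
            "Reverse": "+" if flag == "rev" else "-",
        }
        for sample in design.sample_names:
            rec[ratio_column(sample)] = repr(float(rng.lognormal(0, 0.5)))
            rec[count_column(sample)] = int(2 + rng.poisson(2.0))
        return rec

    for idx in range(1, spike_contaminants + 1):
        records.append(_spiked(idx, "con"))
    for idx in range(1, spike_decoys + 1):
        records.append(_spiked(idx, "rev"))

    table_path = os.path.join(path, "protein_groups.tsv")
    truth_path = os.path.join(path, "truth_labels.tsv")
    pd.DataFrame.from_records(records).to_csv(table_path, sep="\t", index=False)
    dataset.truth_labels.rename_axis("ProteinID").to_frame().to_csv(
        truth_path, sep="\t"
    )
    return table_path, truth_path
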