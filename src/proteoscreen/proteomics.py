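"""Protein-level concordance statistics for label-free intensity tables.

A protein table carries one row per protein (identifier, gene symbol,
unique-peptide count) followed by per-sample intensity columns; a sidecar
condition map assigns samples to conditions.  The module filters on
unique-peptide support, computes treatment/control abundance ratios on the
raw (normalized) intensity scale, and tests group differences with a
two-tailed pooled-variance t-test on arcsinh-transformed intensities.
The arcsinh transform behaves like a log at high intensity but is defined
at zero, which suits label-free LC-MS abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_min_peptides",
    "protein_test",
    "protein_table_tests",
    "passes_protein_criterion",
    "median_center",
    "read_protein_table",
]

META_COLUMNS = ("protein_id", "gene_symbol", "unique_peptides")


def read_protein_table(path, condition_map_path=None):
    """Read a protein TSV (protein_id, gene_symbol, unique_peptides, samples...).

    Returns ``(table, conditions)`` where ``conditions`` is a Series mapping
    sample column to condition label, or ``None`` when no sidecar is given.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"protein table lacks required columns: {missing}")
    conditions = None
    if condition_map_path is not None:
        conditions = pd.read_csv(condition_map_path, sep="\t", index_col=0).iloc[:, 0]
    return table, conditions


def filter_min_peptides(table: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Retain proteins identified with at least *k* unique peptide sequences.

    The conventional retention rule is k=2; k=1 keeps single-peptide
    identifications (some published candidate tables include them).
    """
    if k < 1:
        raise ValueError(f"minimum peptide count must be >= 1, got {k}")
    return table[table["unique_peptides"] >= k].reset_index(drop=True)


def median_center(table: pd.DataFrame, sample_columns: list[str]) -> pd.DataFrame:
    """Optional global normalization: scale each sample to the common median."""
    out = table.copy()
    medians = out[sample_columns].median(axis=0)
    out[sample_columns] = out[sample_columns] * (medians.median() / medians)
    return out


def protein_test(group_a, group_b) -> tuple[float, float]:
    """Abundance ratio and two-tailed pooled t-test p for two intensity groups.

    The ratio is mean(group_b)/mean(group_a) on the untransformed scale
    (treatment over control convention); the p-value comes from an
    equal-variance two-sample t-test on arcsinh-transformed intensities.
    Degenerate zero-variance groups: equal means give p = 1 by convention,
    unequal means p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 intensity values")
    ratio = float(b.mean() / a.mean())
    ta, tb = np.arcsinh(a), np.arcsinh(b)
    if ta.var(ddof=1) == 0.0 and tb.var(ddof=1) == 0.0:
        p = 1.0 if np.isclose(ta.mean(), tb.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(ta, tb, equal_var=True).pvalue)
    return ratio, p


def protein_table_tests(
    table: pd.DataFrame,
    conditions: pd.Series,
    control: str,
    treatment: str,
) -> pd.DataFrame:
    """Per-protein ratio and p-value for treatment vs control.

    Returns the metadata columns plus ``ratio`` and ``p_value``.
    """
    samples_a = [s for s in table.columns if conditions.get(s) == control]
    samples_b = [s for s in table.columns if conditions.get(s) == treatment]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"need >= 2 samples per condition ({control}: {len(samples_a)}, "
            f"{treatment}: {len(samples_b)})"
        )
    results = [
        protein_test(row[samples_a].to_numpy(float), row[samples_b].to_numpy(float))
        for _, row in table.iterrows()
    ]
    out = table[list(META_COLUMNS)].copy()
    out["ratio"] = [r for r, _ in results]
    out["p_value"] = [p for _, p in results]
    return out


def passes_protein_criterion(
    ratio: float,
    p_value: float,
    ratio_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> bool:
    """Concordance rule: abundance ratio above and p below threshold, strictly."""
    return bool(ratio > ratio_threshold and p_value < p_threshold)
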