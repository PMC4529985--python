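"""Per-gene fold changes, the rank-products statistic, and permutation pfp.

The rank-products statistic is the two-class unpaired construction: for each
of the ``n_a * n_b`` replicate pairings between two conditions, every gene's
between-pairing expression ratio is ranked across genes (rank 1 = most
up-regulated for direction ``"up"``, ties averaged), and a gene's statistic
is the geometric mean of its ranks over all pairings.  Consistently
top-ranked genes attain a rank product near 1.

Significance is reported as pfp, the estimated percentage of false-positive
predictions: a permutation null is built by shuffling each pairing's rank
vector across genes, the expected number of null rank products at or below
each observed value is estimated, and divided by the gene's rank position in
the observed ordering.  pfp is not a p-value and may exceed 1; it is never
negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "fold_change",
    "fold_changes",
    "rank_products",
    "rank_products_from_arrays",
    "estimate_pfp",
    "contrast",
    "collapse_to_genes",
    "read_expression",
]

_DIRECTIONS = ("up", "down")


@dataclass
class ExpressionMatrix:
    """Strictly positive intensities for genes (rows) across labelled samples.

    Parameters
    ----------
    values
        Genes x samples DataFrame of normalized, strictly positive
        intensities with unique gene and sample identifiers.
    conditions
        Mapping (pandas Series, index = sample id) of each sample to its
        condition label.  Every column of ``values`` must be covered.
    """

    values: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        missing = [s for s in self.values.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() <= 0).any():
            raise ValueError("expression intensities must be strictly positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def samples_of(self, condition: str) -> list[str]:
        """Sample identifiers assigned to *condition*, in matrix column order."""
        hits = [s for s in self.values.columns if self.conditions[s] == condition]
        if not hits:
            raise KeyError(f"unknown condition: {condition!r}")
        return hits

    def submatrix(self, condition: str) -> np.ndarray:
        return self.values[self.samples_of(condition)].to_numpy(dtype=float)


def read_expression(matrix_path, condition_map_path) -> ExpressionMatrix:
    """Load a TSV matrix (first column gene_id) and a sample->condition TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cmap = pd.read_csv(condition_map_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionMatrix(values=values, conditions=cmap)


def fold_change(expr: ExpressionMatrix, gene: str, cond_a: str, cond_b: str) -> float:
    """Mean intensity in ``cond_b`` over mean intensity in ``cond_a``.

    By the treatment-over-control convention ``cond_a`` is the baseline
    (e.g. untreated control) and ``cond_b`` the treatment.
    """
    if gene not in expr.values.index:
        raise KeyError(f"unknown gene: {gene!r}")
    row = expr.values.loc[gene]
    return float(row[expr.samples_of(cond_b)].mean() / row[expr.samples_of(cond_a)].mean())


def fold_changes(expr: ExpressionMatrix, cond_a: str, cond_b: str) -> pd.Series:
    """Vectorised ``fold_change`` for every gene."""
    a = expr.submatrix(cond_a).mean(axis=1)
    b = expr.submatrix(cond_b).mean(axis=1)
    return pd.Series(b / a, index=expr.gene_ids, name="fc")


def _pairing_rank_matrix(a: np.ndarray, b: np.ndarray, direction: str) -> np.ndarray:
    """Within-pairing ranks, one column per (replicate_a, replicate_b) pairing.

    Rank 1 marks the gene with the largest b/a ratio for ``direction="up"``
    (smallest for ``"down"``); ties are averaged.
    """
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    n_genes, n_a = a.shape
    n_b = b.shape[1]
    cols = []
    for i in range(n_a):
        for j in range(n_b):
            ratio = b[:, j] / a[:, i]
            cols.append(rankdata(-ratio if direction == "up" else ratio))
    return np.column_stack(cols)


def rank_products_from_arrays(a: np.ndarray, b: np.ndarray, direction: str = "up") -> np.ndarray:
    """Rank product per gene from raw replicate arrays (genes x replicates).

    Works for any replicate count >= 1 per group; the public
    :func:`rank_products` enforces the >= 2 replicates a contrast needs.
    """
    ranks = _pairing_rank_matrix(np.asarray(a, float), np.asarray(b, float), direction)
    return np.exp(np.log(ranks).mean(axis=1))


def _contrast_arrays(expr: ExpressionMatrix, cond_a: str, cond_b: str):
    a = expr.submatrix(cond_a)
    b = expr.submatrix(cond_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError(
            f"need >= 2 replicates per condition for a contrast "
            f"({cond_a}: {a.shape[1]}, {cond_b}: {b.shape[1]})"
        )
    return a, b


def rank_products(
    expr: ExpressionMatrix, cond_a: str, cond_b: str, direction: str = "up"
) -> pd.Series:
    """Rank product of each gene for the ``cond_b`` vs ``cond_a`` contrast."""
    a, b = _contrast_arrays(expr, cond_a, cond_b)
    return pd.Series(rank_products_from_arrays(a, b, direction), index=expr.gene_ids, name="rp")


def estimate_pfp(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    direction: str = "up",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank products with permutation-estimated pfp for one contrast.

    The null is built by independently shuffling each pairing's rank vector
    across genes ``n_perm`` times.  For each gene, ``E`` is the average
    number of null rank products at or below its observed value, and
    ``pfp = E / rank position`` in the observed ordering (ascending rank
    product, gene id breaking ties).  A cumulative maximum down the sorted
    list enforces non-decreasing pfp so significance sets are nested.

    Returns a DataFrame indexed by gene with columns ``rp`` and ``pfp``.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    a, b = _contrast_arrays(expr, cond_a, cond_b)
    ranks = _pairing_rank_matrix(a, b, direction)
    n_genes, k = ranks.shape
    rp_obs = np.exp(np.log(ranks).mean(axis=1))

    rng = np.random.default_rng(seed)
    # Null rank products: shuffle every pairing's rank column across genes,
    # independently per permutation.  rng.permuted with axis=1 shuffles each
    # (permutation, pairing) slice along the gene axis.
    log_ranks = np.log(ranks)
    tiled = np.broadcast_to(log_ranks, (n_perm, n_genes, k)).copy()
    tiled = rng.permuted(tiled, axis=1)
    null_rp = np.exp(tiled.mean(axis=2)).ravel()
    null_rp.sort()

    # E = expected count of null rank products <= observed, per permutation.
    e_vals = np.searchsorted(null_rp, rp_obs, side="right") / n_perm

    order = np.lexsort((np.asarray(expr.gene_ids, dtype=object), rp_obs))
    positions = np.empty(n_genes, dtype=float)
    positions[order] = np.arange(1, n_genes + 1)
    pfp = e_vals / positions
    # Step-down monotonicity along the sorted list.
    pfp_sorted = np.maximum.accumulate(pfp[order])
    pfp[order] = pfp_sorted
    pfp = np.clip(pfp, 0.0, None)

    return pd.DataFrame({"rp": rp_obs, "pfp": pfp}, index=expr.gene_ids)


def contrast(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    direction: str = "up",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full contrast table: fold change, rank product and pfp per gene.

    Columns: ``gene_id`` (index), ``direction``, ``fc``, ``rp``, ``pfp``.
    """
    out = estimate_pfp(expr, cond_a, cond_b, direction, n_perm=n_perm, seed=seed)
    out.insert(0, "fc", fold_changes(expr, cond_a, cond_b))
    out.insert(0, "direction", direction)
    out.index.name = "gene_id"
    return out


def collapse_to_genes(contrast_df: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene symbol.

    When several probes map to one symbol, the row with the largest fold
    change in this contrast is retained and carries its rp/pfp (the
    "maximum" convention common in array reporting).  Residual ties break
    on probe identifier to stay deterministic.
    """
    df = contrast_df.copy()
    unmapped = df.index.difference(probe_to_gene.index)
    if len(unmapped):
        warnings.warn(f"{len(unmapped)} probes without a gene symbol were dropped")
        df = df.loc[df.index.intersection(probe_to_gene.index)]
    df["_gene"] = probe_to_gene.reindex(df.index)
    # Stable sort: probe id ascending first, then fc descending, so fc ties
    # resolve to the lexicographically smallest probe.
    df = df.sort_index(kind="mergesort").sort_values("fc", ascending=False, kind="mergesort")
    out = df.groupby("_gene", sort=True).head(1).set_index("_gene")
    out.index.name = "gene_id"
    return out.sort_index()
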