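"""Step-1 specificity screen: treatment-specific up-regulation with protein support.

A gene is a *specific candidate* when, relative to untreated control, its
transcript shows a fold change strictly above the threshold with rank-products
pfp strictly below the significance bound under the treatment, it is NOT
up-regulated past the exclusion threshold under the comparator treatment, and
(when protein evidence is required) a concordant protein abundance increase
is present.  All comparisons are strict: a fold change of exactly 2.0 fails
a 2.0 threshold, and a comparator fold change of 1.98 does not exclude.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .proteomics import passes_protein_criterion

__all__ = ["ScreenCriteria", "STATUSES", "classify_gene", "screen_step1"]

#: Exhaustive, mutually exclusive per-gene outcomes, in evaluation order.
STATUSES = (
    "specific_candidate",
    "excluded_comparator",
    "fails_transcript",
    "no_protein_data",
    "fails_protein",
)


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the candidate screen; all comparisons strict.

    fc_threshold
        Minimum treatment-vs-control transcript fold change (exclusive).
    pfp_threshold
        Maximum rank-products pfp (exclusive).
    comparator_fc_exclusion
        Genes whose comparator-vs-control fold change exceeds this are
        excluded as not treatment-specific.
    protein_ratio_threshold, protein_p_threshold
        Concordant-protein rule: abundance ratio above, t-test p below.
    require_protein
        Whether protein evidence is required (True for primary candidates;
        network-partner re-screening sets it False).
    """

    fc_threshold: float = 2.0
    pfp_threshold: float = 0.05
    comparator_fc_exclusion: float = 2.0
    protein_ratio_threshold: float = 2.0
    protein_p_threshold: float = 0.05
    require_protein: bool = True

    def __post_init__(self) -> None:
        for name in (
            "fc_threshold",
            "pfp_threshold",
            "comparator_fc_exclusion",
            "protein_ratio_threshold",
            "protein_p_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def classify_gene(
    lpon_fc: float,
    lpon_pfp: float,
    ole_fc: float,
    protein: tuple[float, float] | None,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> str:
    """Classify one gene given its two transcript contrasts and optional protein.

    ``protein`` is a ``(ratio, p_value)`` pair or ``None`` when the protein
    was not detected.  Failure statuses are assigned in the fixed order
    comparator exclusion, transcript rule, missing protein, protein rule.
    """
    if ole_fc > criteria.comparator_fc_exclusion:
        return "excluded_comparator"
    if not (lpon_fc > criteria.fc_threshold and lpon_pfp < criteria.pfp_threshold):
        return "fails_transcript"
    if criteria.require_protein:
        if protein is None:
            return "no_protein_data"
        ratio, p = protein
        if not passes_protein_criterion(
            ratio, p, criteria.protein_ratio_threshold, criteria.protein_p_threshold
        ):
            return "fails_protein"
    return "specific_candidate"


def screen_step1(
    lpon_results: pd.DataFrame,
    ole_results: pd.DataFrame,
    protein_results: pd.DataFrame | None,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> tuple[list[str], pd.DataFrame]:
    """Apply the specificity screen over a shared gene universe.

    Parameters
    ----------
    lpon_results, ole_results
        Contrast tables indexed by gene with ``fc`` and ``pfp`` columns
        (treatment vs control, comparator vs control).
    protein_results
        Table with ``gene_symbol``, ``ratio`` and ``p_value`` columns, or
        ``None``; genes without a row have no protein evidence.
    criteria
        Screen thresholds.

    Returns
    -------
    (candidates, status_table)
        Candidates sorted by treatment fold change descending (gene id
        breaking ties), and the full audit table with one status per gene.
    """
    universe = lpon_results.index.intersection(ole_results.index)
    if len(universe) == 0:
        raise ValueError("empty gene universe: contrasts share no genes")

    protein_of: dict[str, tuple[float, float]] = {}
    if protein_results is not None:
        for _, row in protein_results.iterrows():
            protein_of[row["gene_symbol"]] = (float(row["ratio"]), float(row["p_value"]))

    records = []
    for gene in universe:
        lpon_fc = float(lpon_results.at[gene, "fc"])
        lpon_pfp = float(lpon_results.at[gene, "pfp"])
        ole_fc = float(ole_results.at[gene, "fc"])
        protein = protein_of.get(gene)
        status = classify_gene(lpon_fc, lpon_pfp, ole_fc, protein, criteria)
        records.append(
            {
                "gene_id": gene,
                "status": status,
                "lpon_fc": lpon_fc,
                "lpon_pfp": lpon_pfp,
                "ole_fc": ole_fc,
                "protein_ratio": protein[0] if protein else float("nan"),
                "protein_p": protein[1] if protein else float("nan"),
            }
        )
    status_table = pd.DataFrame.from_records(records).set_index("gene_id").sort_index()

    hits = status_table[status_table["status"] == "specific_candidate"]
    hits = hits.sort_index(kind="mergesort").sort_values(
        "lpon_fc", ascending=False, kind="mergesort"
    )
    return list(hits.index), status_table
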