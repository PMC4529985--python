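"""Ranked gene-set enrichment over a candidate-plus-partners universe.

Genes are ranked by interaction confidence (target gene first).  For a term
annotating ``B`` of the ``N`` ranked genes, every prefix depth ``n`` is
scanned; with ``b`` term genes among the top ``n``, the over-representation
is summarised by

* the enrichment ratio ``(b/n) / (B/N)``, and
* the hypergeometric upper-tail probability ``P(X >= b)`` for X ~
  Hypergeometric(N, B, n), computed by exact rational summation.

The reported p-value per term is the minimum tail over all prefix depths
(the minimum-hypergeometric, or mHG, statistic); an exact correction for
having scanned all depths is available via :func:`mhg_corrected_p`.
Benjamini-Hochberg adjustment across terms yields q-values.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "enrichment_ratio",
    "hypergeom_tail",
    "min_hypergeom",
    "mhg_corrected_p",
    "bh_adjust",
    "ranked_gene_list",
    "read_annotations",
    "enrich_all",
]


def _check_bounds(N: int, B: int, n: int, b: int) -> None:
    if not (1 <= n <= N):
        raise ValueError(f"need 1 <= n <= N, got n={n}, N={N}")
    if not (0 <= B <= N):
        raise ValueError(f"need 0 <= B <= N, got B={B}, N={N}")
    if not (0 <= b <= min(n, B)):
        raise ValueError(f"need 0 <= b <= min(n, B), got b={b}, n={n}, B={B}")


def enrichment_ratio(N: int, B: int, n: int, b: int) -> float:
    """Over-representation ratio ``(b/n) / (B/N)``.

    N is the ranked-universe size, B the term's genes within it, n the
    prefix depth, b the term genes among the top n.  ``B = 0`` has no
    defined baseline and returns NaN rather than raising.
    """
    _check_bounds(N, B, n, b)
    if B == 0:
        return float("nan")
    return (b / n) / (B / N)


def _tail_fraction(N: int, B: int, n: int, b: int) -> Fraction:
    denom = comb(N, n)
    total = sum(comb(B, k) * comb(N - B, n - k) for k in range(b, min(n, B) + 1))
    return Fraction(total, denom)


def hypergeom_tail(N: int, B: int, n: int, b: int) -> float:
    """Exact upper tail ``P(X >= b)``, X ~ Hypergeometric(N, B, n).

    Evaluated by rational summation over the support (no normal
    approximation), then converted to float.
    """
    _check_bounds(N, B, n, b)
    if b == 0:
        return 1.0
    return float(_tail_fraction(N, B, n, b))


def min_hypergeom(flags) -> tuple[int, int, float]:
    """Minimum hypergeometric tail over every prefix of a ranked flag vector.

    ``flags`` marks term membership down the ranked list.  Returns
    ``(n_star, b_star, p_min)`` for the depth with the smallest tail
    probability; ties go to the smallest depth.  An all-zero vector gives
    ``p_min = 1.0`` at depth 1.
    """
    flags = np.asarray(flags, dtype=bool)
    N = flags.size
    if N < 1:
        raise ValueError("ranked flag vector must be non-empty")
    B = int(flags.sum())
    best = (1, int(flags[0]), hypergeom_tail(N, B, 1, int(flags[0])))
    b = int(flags[0])
    for n in range(2, N + 1):
        b += int(flags[n - 1])
        p = hypergeom_tail(N, B, n, b)
        if p < best[2]:
            best = (n, b, p)
    return best


def mhg_corrected_p(flags) -> float:
    """Exact correction of the minimum-hypergeometric statistic.

    The minimum tail over all prefix depths is itself a statistic; its null
    distribution over uniformly random rankings is computed exactly by
    counting monotone lattice paths (one step per ranked gene, up = member)
    that avoid the rejection region ``{(n, b): P(X >= b) <= p_min}``.
    Returns ``P(mHG <= p_min)`` under the null.
    """
    flags = np.asarray(flags, dtype=bool)
    N = flags.size
    B = int(flags.sum())
    _, _, p_min = min_hypergeom(flags)
    if B == 0 or B == N:
        return 1.0
    p_min_frac = _tail_fraction(*_best_cell(flags))
    # Path counting: w[b] = number of prefixes of length n with b members
    # that never entered the rejection region.
    w = [0] * (B + 1)
    w[0] = 1
    for n in range(1, N + 1):
        for b in range(min(n, B), -1, -1):
            cnt = w[b] + (w[b - 1] if b >= 1 else 0)
            if cnt and _tail_fraction(N, B, n, b) <= p_min_frac:
                cnt = 0
            w[b] = cnt
    surviving = w[B]
    return float(1 - Fraction(surviving, comb(N, B)))


def _best_cell(flags) -> tuple[int, int, int, int]:
    flags = np.asarray(flags, dtype=bool)
    N = flags.size
    B = int(flags.sum())
    n_star, b_star, _ = min_hypergeom(flags)
    return N, B, n_star, b_star


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ranked_gene_list(target: str, partner_scores: dict[str, float]) -> list[str]:
    """Rank a candidate's neighbourhood: target first, partners by score.

    Partners are ordered by confidence score descending, gene identifier
    breaking ties, which keeps the ranking deterministic.
    """
    ranked = [target] + sorted(partner_scores, key=lambda g: (-partner_scores[g], g))
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked gene list contains duplicates")
    return ranked


def read_annotations(path, names_path=None):
    """Two-column TSV (term_id, gene_id) -> dict of term -> gene set.

    Returns ``(annotations, names)``; ``names`` maps term to description and
    is empty when no names file is given.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["term_id", "gene_id"], comment="#")
    annotations = {t: set(g) for t, g in df.groupby("term_id")["gene_id"]}
    names: dict[str, str] = {}
    if names_path is not None:
        ndf = pd.read_csv(names_path, sep="\t", header=None, names=["term_id", "name"], comment="#")
        names = dict(zip(ndf["term_id"], ndf["name"]))
    return annotations, names


def enrich_all(
    ranked: list[str],
    annotations: dict[str, set[str]],
    alpha: float = 0.05,
    names: dict[str, str] | None = None,
    corrected: bool = False,
) -> pd.DataFrame:
    """Ranked enrichment of every term against the ranked universe.

    For each term with at least one gene in the universe, the minimum
    hypergeometric tail over all prefix depths gives the p-value (or its
    exact multiple-threshold correction when ``corrected``); q-values are
    BH-adjusted over all tested terms.  The result keeps terms with
    ``p < alpha``, sorted by p ascending then term id.

    Columns: term_id, description, N, B, n, b, enrichment, p_value, q_value.
    """
    if not ranked:
        raise ValueError("ranked gene list is empty")
    names = names or {}
    N = len(ranked)
    in_list = {g: i for i, g in enumerate(ranked)}

    rows = []
    for term in sorted(annotations):
        members = annotations[term] & in_list.keys()
        B = len(members)
        if B == 0:
            continue
        flags = np.zeros(N, dtype=bool)
        for g in members:
            flags[in_list[g]] = True
        n_star, b_star, p_min = min_hypergeom(flags)
        p = mhg_corrected_p(flags) if corrected else p_min
        rows.append(
            {
                "term_id": term,
                "description": names.get(term, ""),
                "N": N,
                "B": B,
                "n": n_star,
                "b": b_star,
                "enrichment": enrichment_ratio(N, B, n_star, b_star),
                "p_value": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "description", "N", "B", "n", "b",
                "enrichment", "p_value", "q_value",
            ]
        )
    out = pd.DataFrame.from_records(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out = out[out["p_value"] < alpha]
    out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return out
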