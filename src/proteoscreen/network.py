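"""Interaction-partner retrieval and transcriptomic re-screening.

Consumes a local edge table in the STRING ``protein.links`` dialect
(``protein1 protein2 combined_score``, space- or tab-separated; scores either
integers on 0-1000 or probabilities on 0-1).  High-confidence partners of a
candidate (combined score >= 0.900 on the fractional scale, inclusive) are
re-screened with the same transcript rules as the primary screen, but
without requiring protein evidence — this rescues partners for which no
protein was detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .screen import ScreenCriteria, classify_gene

__all__ = [
    "InteractionNetwork",
    "load_interactions",
    "partners",
    "crossval_partners",
    "final_candidates",
    "read_aliases",
]


@dataclass
class InteractionNetwork:
    """Undirected scored interaction graph.

    ``graph`` edge attribute ``score`` holds the combined score on the
    declared ``scale`` ("integer" for 0-1000, "fractional" for 0-1);
    :meth:`fractional_score` converts either to 0-1.
    """

    graph: nx.Graph
    scale: str  # "integer" | "fractional"

    def fractional_score(self, u: str, v: str) -> float:
        s = self.graph.edges[u, v]["score"]
        return s / 1000.0 if self.scale == "integer" else float(s)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def load_interactions(path) -> InteractionNetwork:
    """Parse a STRING-links edge file into an :class:`InteractionNetwork`.

    Self-edges are dropped; duplicate (including symmetric) pairs collapse
    to the maximum score.  The score scale is auto-detected: all scores
    <= 1 means fractional, <= 1000 integer, larger is an error.
    """
    graph = nx.Graph()
    max_score = 0.0
    with open(path) as fh:
        header = fh.readline().split()
        expected = ["protein1", "protein2", "combined_score"]
        if [h.strip().lower() for h in header[:3]] != expected:
            raise ValueError(f"expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            u, v, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(f"{path}: bad score at line {lineno}: {raw!r}") from exc
            if score < 0:
                raise ValueError(f"{path}: negative score at line {lineno}")
            if u == v:
                continue
            max_score = max(max_score, score)
            if graph.has_edge(u, v):
                graph.edges[u, v]["score"] = max(graph.edges[u, v]["score"], score)
            else:
                graph.add_edge(u, v, score=score)
    if max_score <= 1.0:
        scale = "fractional"
    elif max_score <= 1000.0:
        scale = "integer"
    else:
        raise ValueError(f"{path}: scores exceed 1000, unknown scale")
    return InteractionNetwork(graph=graph, scale=scale)


def partners(network: InteractionNetwork, gene: str, min_confidence: float = 0.900) -> set[str]:
    """Neighbours of *gene* at combined score >= ``min_confidence`` (inclusive).

    ``min_confidence`` is on the fractional 0-1 scale regardless of how the
    file stored scores.  An unknown gene yields an empty set with a warning.
    """
    if gene not in network.graph:
        warnings.warn(f"gene {gene!r} not present in the interaction network")
        return set()
    return {
        nbr
        for nbr in network.graph.neighbors(gene)
        if network.fractional_score(gene, nbr) >= min_confidence
    }


def crossval_partners(
    partner_ids,
    lpon_results: pd.DataFrame,
    ole_results: pd.DataFrame,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> pd.DataFrame:
    """Re-screen interaction partners with the transcript-only rules.

    Each partner is classified with exactly the Step-1 transcript
    sub-criteria (fold change, pfp, comparator exclusion); protein evidence
    is not required at this stage.  Partners absent from the contrast
    tables are reported with verdict ``unevaluable`` rather than dropped.

    Returns a DataFrame indexed by partner id with columns ``lpon_fc``,
    ``lpon_pfp``, ``ole_fc``, ``verdict``.
    """
    transcript_only = ScreenCriteria(
        fc_threshold=criteria.fc_threshold,
        pfp_threshold=criteria.pfp_threshold,
        comparator_fc_exclusion=criteria.comparator_fc_exclusion,
        protein_ratio_threshold=criteria.protein_ratio_threshold,
        protein_p_threshold=criteria.protein_p_threshold,
        require_protein=False,
    )
    columns = ["partner_id", "lpon_fc", "lpon_pfp", "ole_fc", "verdict"]
    if not partner_ids:
        return pd.DataFrame(columns=columns).set_index("partner_id")
    records = []
    for pid in sorted(partner_ids):
        if pid not in lpon_results.index or pid not in ole_results.index:
            records.append(
                {
                    "partner_id": pid,
                    "lpon_fc": float("nan"),
                    "lpon_pfp": float("nan"),
                    "ole_fc": float("nan"),
                    "verdict": "unevaluable",
                }
            )
            continue
        lpon_fc = float(lpon_results.at[pid, "fc"])
        lpon_pfp = float(lpon_results.at[pid, "pfp"])
        ole_fc = float(ole_results.at[pid, "fc"])
        status = classify_gene(lpon_fc, lpon_pfp, ole_fc, None, transcript_only)
        verdict = "retained" if status == "specific_candidate" else status
        records.append(
            {
                "partner_id": pid,
                "lpon_fc": lpon_fc,
                "lpon_pfp": lpon_pfp,
                "ole_fc": ole_fc,
                "verdict": verdict,
            }
        )
    return pd.DataFrame.from_records(records).set_index("partner_id")


def final_candidates(
    step1_candidates,
    partner_verdicts: pd.DataFrame,
    lpon_results: pd.DataFrame | None = None,
) -> list[str]:
    """Union of primary candidates and retained partners, deterministically ordered.

    Ordering is by treatment fold change descending (taken from
    ``lpon_results`` when given, else from the verdict table for partners),
    then lexicographic.
    """
    retained = list(partner_verdicts.index[partner_verdicts["verdict"] == "retained"])
    members = dict.fromkeys(list(step1_candidates) + retained)

    def fc_of(gene: str) -> float:
        if lpon_results is not None and gene in lpon_results.index:
            return float(lpon_results.at[gene, "fc"])
        if gene in partner_verdicts.index:
            return float(partner_verdicts.at[gene, "lpon_fc"])
        return float("-inf")

    return sorted(members, key=lambda g: (-fc_of(g), g))


def read_aliases(path) -> pd.Series:
    """Two-column TSV mapping network identifiers to gene symbols."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "gene"], comment="#")
    return df.set_index("alias")["gene"]
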