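"""Ranked minimum-hypergeometric enrichment over a candidate neighbourhood.

Ranks the worked example's 33-gene universe (FGA first, partners by
interaction confidence), scans every prefix depth per term, and reports
the enrichment ratio (b/n)/(B/N) at the p-optimal depth with BH q-values.
"""

from proteoscreen import enrich_all, partners, ranked_gene_list
from proteoscreen.pipeline import worked_example_tables

lpon, ole, protein, network, annotations, names = worked_example_tables()

scores = {p: network.fractional_score("FGA", p) for p in partners(network, "FGA")}
ranked = ranked_gene_list("FGA", scores)
print(f"ranked universe: N = {len(ranked)} (target {ranked[0]} first)")

result = enrich_all(ranked, annotations, alpha=0.05, names=names)
cols = ["term_id", "description", "p_value", "q_value", "enrichment", "N", "B", "n", "b"]
with __import__("pandas").option_context("display.width", 120):
    print(result[cols].to_string(index=False, float_format=lambda x: f"{x:.3g}"))
# Each row: of the B term genes in the 33-gene universe, b fall within the
# top n ranks; the ratio (b/n)/(B/N) is their over-representation at the
# depth where the exact hypergeometric tail is smallest.
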