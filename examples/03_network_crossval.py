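"""Partner cross-validation on the built-in worked example.

The worked-example tables encode published per-gene summary statistics for
a fibrinogen-centred screen: two primary candidates (FGA, FDFT), the
32-gene high-confidence neighbourhood of FGA, and the comparator fold
changes that exclude two of its four up-regulated partners.
"""

from proteoscreen import crossval_partners, final_candidates, partners, screen_step1
from proteoscreen.pipeline import worked_example_tables

lpon, ole, protein, network, annotations, names = worked_example_tables()

candidates, _ = screen_step1(lpon, ole, protein)
print("Step 1 candidates:", candidates)

fga_partners = partners(network, "FGA", min_confidence=0.900)
print(f"FGA has {len(fga_partners)} partners at combined score >= 0.900")

verdicts = crossval_partners(fga_partners, lpon, ole)
print(verdicts[verdicts["verdict"] != "fails_transcript"].round(4))

final = final_candidates(["FGA"], verdicts, lpon)
print("final coagulation candidate set:", final)
# FGB and FGG pass the transcript-only re-screen (rescued despite missing
# or sub-threshold protein data); FGL1 and CST3 are excluded because the
# comparator treatment also up-regulates them >2-fold.
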