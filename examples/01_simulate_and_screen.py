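"""Simulate a three-condition experiment and run the Step-1 specificity screen.

Generates a 300-gene log-normal intensity matrix (control, treatment,
comparator; triplicates) with 8 planted treatment-specific genes
(2.2-fold) and 8 genes shared with the comparator (2.3-fold), plus a
matched protein table; then screens for treatment-specific candidates.
"""

from proteoscreen import (
    SimulationConfig,
    contrast,
    generate_expression,
    generate_proteomics,
    protein_table_tests,
    screen_step1,
)

config = SimulationConfig(n_genes=300, n_specific=8, n_shared=8, noise_sd=0.05, seed=42)
expr, truth = generate_expression(config)

lpon = contrast(expr, "control", "LPON", n_perm=500, seed=42)
ole = contrast(expr, "control", "OLE", n_perm=500, seed=43)
protein = protein_table_tests(
    generate_proteomics(config, truth), expr.conditions, "control", "LPON"
)

candidates, status = screen_step1(lpon, ole, protein)

print("status counts:", status["status"].value_counts().to_dict())
print("candidates:", candidates)
print("planted specific genes:", truth.specific_genes)
hit = len(set(candidates) & set(truth.specific_genes))
print(f"{hit}/{len(truth.specific_genes)} planted specific genes recovered; "
      f"{len(set(candidates) & set(truth.shared_genes))} shared genes leaked")
# The screen keeps genes >2-fold up (pfp<0.05) under the treatment but not
# the comparator, with concordant protein evidence; the counts above show
# how many planted effects survive triplicate sampling noise.
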