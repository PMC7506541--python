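"""ELS, GELS and IRS from binding predictions and HLA frequencies.

Simulates a binding-prediction table for two frameshift peptides,
combines it with population HLA allele frequencies, and prints the
score hierarchy at p_binding = 0.5 and the 500 nM affinity threshold.
"""

from msiedit import (
    count_table,
    generate_frameshift_peptides,
    score_table,
    simulate_cds,
    simulate_prediction_table,
)
from msiedit.immunoscore import HlaFrequencyTable

cds, locus = simulate_cds("CASP5", "A", 10, seed=3)
peptides = generate_frameshift_peptides(cds, locus)
predictions = simulate_prediction_table(peptides, seed=3)
counts = count_table(predictions)
print(f"{len(predictions)} predictions over {counts.shape[0]} (peptide, allele) pairs")

freqs = HlaFrequencyTable(
    population="USA-Euro",
    frequencies={"A*01:01": 0.16, "A*02:01": 0.28, "A*03:01": 0.13, "A*24:02": 0.09,
                 "A*26:01": 0.03, "B*07:02": 0.14, "B*08:01": 0.12, "B*27:05": 0.04,
                 "B*39:01": 0.02, "B*40:01": 0.05, "B*58:01": 0.01, "B*15:01": 0.05},
    sample_size=39_689,
)

scores = score_table(counts, freqs, p_mut={"CASP5": 0.6}, p_binding=0.5, threshold=500)
for _, row in scores.iterrows():
    print(f"{row['peptide_id']}: GELS_A {row['GELS_A']:.3f}  GELS_B {row['GELS_B']:.3f}  "
          f"GELS {row['GELS']:.3f}  IRS {row['IRS']:.3f}")
# GELS is the probability that a random member of the population carries
# at least one HLA allele with at least one true binder in the peptide;
# IRS multiplies it by the mutation frequency (here 60%), ranking
# candidates by joint likelihood of being present and presentable.
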