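"""Pairwise co-occurrence / mutual-exclusivity screen.

Builds the O/LO incidence matrix over genes mutated in at least four
patients and runs the unadjusted two-sided Fisher screen, printing the
strongest pairs first.
"""

from amlreclass import build_matrix, fixture_cohort, pairwise_screen
from amlreclass.filtering import clinical_subset

patients, variants = fixture_cohort()
matrix = build_matrix(clinical_subset(variants), min_mutated=4,
                      patients=[p.patient_id for p in patients])
print(f"incidence matrix: {matrix.shape[0]} patients x {matrix.shape[1]} genes")

results = pairwise_screen(matrix)
print(f"\ntop pairs of {len(results)} screened (unadjusted two-sided Fisher):")
print(f"{'gene A':8s} {'gene B':8s} {'n both':>6s} {'OR':>8s} {'p':>8s}  direction")
for r in results[:8]:
    odds = "inf" if r.odds_ratio == float("inf") else f"{r.odds_ratio:.2f}"
    print(f"{r.gene_a:8s} {r.gene_b:8s} {r.n11:>6d} {odds:>8s} {r.p_two_sided:>8.4f}"
          f"  {r.direction.value}")
print("\nAn odds ratio above 1 with p <= 0.05 flags co-occurring gene pairs; "
      "below 1, mutual exclusivity.")
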