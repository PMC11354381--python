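"""Run the somatic-variant filtering cascade on a hand-built table.

Each variant violates (or passes) one rule; the audit names the failed
rule per row, which is what a reviewer checks before trusting the kept
set.
"""

from amlreclass import GeneSetRegistry, filter_table
from amlreclass.types import VariantCall


def v(**kw):
    base = dict(patient_id="P1", gene="TET2", variant_class="SNV", impact="HIGH",
                alt_reads=30, vaf=0.35, pop_af=0.0, cadd=25.0,
                oncogenicity="ONCOGENIC", paired_normal=True)
    base.update(kw)
    return VariantCall(**base)


variants = [
    v(gene="DNMT3A"),                                      # passes everything
    v(impact="LOW"),                                       # fails impact
    v(alt_reads=5),                                        # fails min_reads (>= 8)
    v(vaf=0.04, paired_normal=False),                      # fails min_vaf (> 0.05)
    v(pop_af=0.01, paired_normal=False),                   # fails max_popaf (<= 0.001)
    v(gene="ASXL2", cadd=12.0),                            # extended list: CADD must be > 15
    v(oncogenicity="LIKELY_BENIGN"),                       # curation gate
]

kept, audit = filter_table(variants, GeneSetRegistry.default())
print(f"kept {len(kept)}/{len(variants)} variants\n")
for d in audit:
    status = "KEPT" if d.kept else "drop: " + ",".join(d.failed_rules)
    print(f"  {d.variant.gene:8s} {status}")
print("\nOnly the first variant survives; every other row names the single "
      "rule it violates.")
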