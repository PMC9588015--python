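"""Design one patient's micro-panel from a somatic variant table.

Applies the post-calling filters (population AF, MQ0 fraction, depth, known
and low-confidence variants), then selects every non-silent TP53 variant
plus the highest-VAF others, up to six amplicons.
"""

from micropanel import CohortConfig, simulate_cohort
from micropanel.panel_design import (
    FilterConfig, PanelConfig, build_pools, filter_variants, select_panel,
)

truth = simulate_cohort(CohortConfig(n_patients=1, seed=12))[0]
variants = truth.variant_profile
passing = filter_variants(variants, FilterConfig())
panel = select_panel(passing, PanelConfig())
build_pools([panel])

print(f"patient {truth.patient_id}: {len(variants)} somatic variants, "
      f"{len(passing)} pass filters")
print(f"panel size: {panel.size} (pool {panel.pool_id})")
for t in panel.targets:
    v = t.variant
    tag = "TP53 rule" if v.is_nonsilent_tp53 else "top VAF"
    print(f"  {v.gene_symbol:8s} {v.chrom}:{v.pos} {v.ref_allele}>{v.alt_allele} "
          f"tissue VAF {v.tissue_vaf:.2f}  [{tag}]  "
          f"amplicon [{t.amplicon_start}, {t.amplicon_end})")

# Every non-silent TP53 variant is always on the panel; remaining slots go
# to the highest tumor-tissue VAF variants, the ones most likely to be
# detectable in blood.
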