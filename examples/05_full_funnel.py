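"""The full funnel end to end on the bundled study tables.

Runs haplotype -> proteome background -> CV -> correlation -> SNP
annotation and prints the per-stage attrition and the final candidates.
"""

import cholscreen as cs

study = cs.load_study_tables()
report = cs.run_funnel_tables(
    study.haplotypes, study.proteome,
    correlation_grid=study.correlations,
    snp_tables=study.snp_tables,
)

for stage in report.stages:
    print(f"{stage.name:<24} retained {len(stage.retained):>2}"
          f"  removed {len(stage.removed):>2}")
print(f"\nfinal candidates: {', '.join(report.final_candidates)}")
for gene, ann in report.annotations.items():
    print(f"  {gene}: SNP rows per category {ann['snp_counts']}")
print("\n--- markdown report (truncated) ---")
print("\n".join(cs.render_report(report, "markdown").splitlines()[:12]))
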