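"""Stage 4: categorize GWAS association rows for the final candidates.

Each (variant, phenotype, p) row is kept when p <= 0.05 and classified
into alcohol-related, liver-related or developmental disorders by the
packaged ordered rule set (ICD prefixes first, then keywords, then a
developmental fallthrough).
"""

import cholscreen as cs

for gene in ("Cept1", "Slc44a1"):
    records = cs.load_snp_associations(gene)
    kept = cs.filter_by_pvalue(records, p_max=0.05)
    counts = cs.count_categories(cs.categorize_records(kept), gene)
    print(f"{gene}: {len(records)} rows, {counts.total_rows} at p <= 0.05")
    for cat, n in counts.counts.items():
        print(f"  {cat:<14} {n}")
# Rows, not unique variants, are counted: a variant reported with two
# phenotypes contributes to two categories.
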