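"""Stage 1: haplotype variability across the four-strain panel.

Loads the bundled 22-gene x 4-strain haplotype-call table and keeps the
genes whose parental-origin calls differ among the strains — only those
can explain strain-specific differences in choline metabolism.
"""

import cholscreen as cs

table = cs.load_haplotype_calls()
retained, removed = cs.filter_by_haplotype(table)

print(f"panel strains: {table.strains}")
print(f"{len(retained)} of {len(table.genes)} genes are haplotype-variable:")
print("  " + ", ".join(retained))
print(f"{len(removed)} genes removed, e.g.:")
for gene in list(removed)[:3]:
    print(f"  {gene}: {removed[gene]}")
# A retained gene has >= 2 distinct codes (B6/D2/H/R) across the panel;
# NV rows and uniform rows carry no mappable signal and are dropped.
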