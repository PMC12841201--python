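# Ordered phenotype-label classification rules for GWAS association rows.
# First matching rule wins; matching is case-insensitive.  ICD-style code
# prefixes come before keyword rules so that e.g. "K70 Alcoholic liver
# disease" lands in the alcohol category, not the liver one.  Rows matching
# no rule fall through to the developmental category.
rules:
  - match: prefix
    pattern: "K70"
    category: alcohol
  - match: prefix
    pattern: "F10"
    category: alcohol
  - match: substring
    pattern: "alcohol"
    category: alcohol
  - match: substring
    pattern: "liver"
    category: liver
  - match: substring
    pattern: "gamma glutamyltransferase"
    category: liver
  - match: substring
    pattern: "lipid"
    category: liver
  - match: substring
    pattern: "cholesterol"
    category: liver
  - match: substring
    pattern: "triglyceride"
    category: liver
fallthrough: developmental
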