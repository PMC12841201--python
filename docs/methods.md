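# Methods

## The screening model

The package operationalises a sequential candidate-gene funnel over a
BXD recombinant-inbred mouse panel. Each stage applies one elimination
criterion to the surviving gene set, so the retained sets are nested by
construction and every elimination is recorded with its stage and
reason. The stages and their statistical content are described below,
followed by the synthetic-data model, numerical choices, and known
limitations.

### Percent reduction in ethanol-induced cell death

Cell death is measured per litter (the litter, not the embryo, is the
unit of analysis); litter means are averaged to strain means per
(region, treatment, choline dose) group. The maltose/dextrin control
groups at all choline doses are pooled unconditionally into a single
control mean per strain and region, weighting by litter count so that
pooling and aggregation commute. The statistic for a strain, region and
treated dose is

    rho = (CE - MD) / (E0 - MD)

with CE the choline+ethanol mean, E0 the ethanol-without-choline mean
and MD the pooled control mean. `100·rho` is the percentage of
ethanol-induced cell death *remaining* under choline; `100·(1 − rho)` is
the percentage *reduction*. The two conventions are exact complements
(they sum to 100) and the literature is not always careful about which
one a "percent reduction" axis carries, so the package computes either,
stamps the convention into every `ReductionMatrix`, and defaults to
REMAINING — the formula exactly as written, with no reinterpretation.
Values are never clamped: choline groups below control give negative
remaining percentages, and treated groups above the ethanol baseline
give values over 100; both are informative. `E0 = MD` means there was no
ethanol-induced cell death to normalise by and raises a dedicated error
rather than returning an unstable ratio.

The statistic is invariant under common positive affine rescaling of the
three means, so it is insensitive to staining units and background
offsets shared by all groups.

### Haplotype variability (stage 1)

A gene is variable when at least two distinct codes from {B6, D2, H, R}
appear among the panel strains. H (heterozygous) and R (recombinant)
count as states of their own. NV is a gene-level flag meaning the whole
panel shows no variation; mixing NV with per-strain codes violates the
table invariant and is rejected at read time and again in the decision
function. A uniform-H row counts as a single state and is therefore not
variable; the convention is a documented choice, since a row that is
heterozygous everywhere carries no *between-strain* contrast to map.
Variability is monotone in the panel: adding strains can only add
distinct codes.

### Proteome filters (stages 2–3)

Abundances are on a log2 scale (a difference of 1.0 is a two-fold
change). Detection requires every non-missing panel value to be strictly
above the background threshold (default 7.0); the all-strains reading is
the conservative choice where a panel-mean reading would also be
defensible. A gene additionally needs at least two non-missing values —
variability is meaningless from one point. Strains with missing values
are excluded gene-wise rather than failing the gene, which is what makes
a panel member absent from the reference proteome (here one of four
strains) drop out of the analysis without discarding the genes.

The variability criterion is the coefficient of variation,
`100 · s / |x̄|` with the sample (n − 1) standard deviation. The n − 1
denominator is what reproduces the three nonzero published CVs to all
printed decimals (1.136, 0.707, 1.200), which pins down the estimator
the original analysis used. Reporting rounds half-away-from-zero to
3 decimals; comparisons use full precision. The retention test is
`CV > tolerance` with a 1e−9 default — an exact-zero test with a
numerical guard, since the criterion as stated is "nonzero variation",
not "variation above a floor".

### Correlation screen (stage 4)

Pearson's product-moment r between per-strain protein abundance and the
percent statistic, one coefficient per (region ∈ {brainstem, forebrain})
× (dose ∈ {100, 250} mg/kg) condition. Strains missing either value are
dropped per cell; at least three common strains are required, and with
so few points the companion p-value (two-sided t on n − 2 df) is
reported for information only and plays no part in selection. Zero
variance in either variable raises rather than silently skipping the
cell — a flat protein row should have been caught by the CV stage, so
reaching a degenerate correlation indicates an inconsistent input.

Selection: r strictly greater than 0.7 in at least 3 of the 4
conditions. The default compares signed r, reading the cutoff literally;
an absolute-value mode (`use_absolute_r`) is provided for screens that
treat strong negative trends as equally interesting, and signed
selection is never more permissive than absolute selection at the same
threshold. Ties at the threshold fail — the criterion is "over 0.7".
Whether a positive r means choline works better or worse for
high-expressing strains depends on the convention of the percent axis;
the package deliberately does not hard-code that interpretation, which
is why the convention travels with the matrix.

The pipeline's correlation stage accepts either litter-level
observations (computing the matrix internally) or a precomputed
coefficient grid. The grid route exists because published screens often
print the coefficient grid while the underlying phenotype values live in
an appendix or are not reproduced at all; the two routes select
identically whenever the grid equals the computed coefficients, and a
test asserts exactly that on synthetic data.

### SNP categorization (stage 5)

Association rows are (variant, phenotype label, p). Rows with p
strictly over 0.05 are excluded (0.05 itself is retained). Labels are
classified by an ordered rule list, first match wins, case-insensitive:
ICD-style code prefixes (K70, F10 → alcohol) come first, then keyword
rules (liver, gamma glutamyltransferase, lipid, cholesterol,
triglyceride → liver; alcohol → alcohol), then a developmental
fallthrough. Keyword matches must start at a word boundary: "alcohol"
matches "Alcoholism" but "liver" must not match "delivery" — without the
boundary rule, labor-and-delivery phenotypes would be silently counted
as liver disorders. The rule set ships as an editable YAML file; it is
the minimal ordered set consistent with all six published per-category
counts, and the counting unit is rows, not unique variants (a variant
reported with two phenotypes contributes twice), which is likewise
required for the published totals to balance. This stage annotates the
final candidates; it eliminates nothing.

The numeric pre-pass normalises published notation — the typographic
minus (U+2212), the multiplication sign and `x 10^k^` superscript markup
— to ASCII `e` notation before parsing, and is idempotent.

## Synthetic data

The generator emulates the structure the funnel assumes, with a planted
ground truth so recovery is testable:

- **Haplotypes**: each gene is variable with probability `p_variable`
  (default 12/22, matching the real panel's fraction); variable genes
  draw per-strain codes with small heterozygous/recombinant
  probabilities (0.05 each) and are forced to ≥ 2 distinct codes;
  non-variable genes are NV with probability 0.7 (7 of the 10
  non-variable genes in the real panel are NV) or uniform parental
  otherwise.
- **Proteome**: per-gene mean abundance ~ N(16, 2²) on the log2 scale
  with across-strain spread 0.3; genes are absent from the table with
  probability 0.3, and by default one strain has no proteome data at
  all, mirroring the real panel's coverage. Planted genes are always
  present, variable and above background by construction.
- **Cell death**: control groups have mean 20 (arbitrary staining
  units), the ethanol-only group 40, and choline+ethanol groups sit at
  the mean implied by the strain's expected reduction percent:
  `100·(1 − rho0) + beta_region · (x − x̄)` with baseline remaining
  fraction rho0 = 0.4 and x the strain's log2 abundance of the planted
  gene. Slopes are set per region (defaults 50 and 35 %/log2-unit) so a
  gene can pass in one region only, exercising the 3-of-4 rule. Litter
  counts are uniform on {5,…,8} per group, matching the study design;
  litter means are normal with sd 2 (floored at 0 to respect the
  non-negativity of a death count mean — a negligible truncation at
  these means). With these defaults the planted reduction-percent signal
  is roughly three times the aggregation noise.
- **GWAS rows**: labels drawn from per-category pools styled after real
  catalog exports (ICD-coded and free-text), p-values log-uniform below
  the cut plus a configurable fraction above it.

All generators are pure functions of the parameter object (which carries
the seed); independent child streams per table keep each generator
reproducible on its own.

What the synthetic model does **not** emulate: linkage between
neighbouring genes' haplotypes, correlated proteome noise across genes,
count-valued (rather than Gaussian) litter means, dose-response
structure beyond a shared slope, and any real LD structure among GWAS
variants. Passing the recovery tests therefore shows the funnel's logic
and arithmetic are sound under its own assumptions, not that the
criteria are well-powered on real data — with three or four strains per
correlation, power is intrinsically low, which is also why the published
analysis treats the screen as hypothesis-generating.

## Numerical and design choices

- Missing token is exactly "n/a" (case-insensitive); empty cells also
  map to missing. Gene symbols match case-insensitively but are stored
  as read (real tables mix capitalisations); strain ids match exactly.
- CV uses |mean| in the denominator so the invariant CV ≥ 0 holds even
  for hypothetical negative-mean inputs; abundances in practice are
  far positive.
- `pearson_r` is computed from centred vectors and clipped to [−1, 1]
  against floating-point overshoot; tests verify agreement with an
  explicit-sums evaluation to 1e−12.
- Rounding for reported CVs is decimal half-away-from-zero, not
  banker's rounding, to match how the published values were printed.
- Funnel determinism: identical inputs and config give byte-identical
  reports (logs excepted); stage order is fixed; a stage failure raises
  a `PipelineStageError` carrying the partial report with the failed
  stage marked ABORTED.
- The header heuristic for haplotype files treats a first row consisting
  entirely of haplotype codes as data (missing header); a single
  code-like column name is allowed because "B6" is both a strain name
  and a code.
- Monte-Carlo problem sizes (200 acceptance replicates, 500 in the null
  test, panels of 4 strains × 4 genes) were chosen to give stable rate
  estimates at small cost; the comparison of planted vs. null selection
  rates uses a pooled 3-standard-error margin.

## Limitations

- The litter-level phenotype values behind the published coefficient
  grid are not reproduced in the source tables, so the grid is consumed
  as printed in the reproduce-the-study path; full computation from
  observations is exercised on synthetic data only.
- The published per-condition correlation p-value ranges are not
  derivable from 3-strain correlations under the standard t test; the
  package's p-values are the standard ones and are informational output
  only, never a selection criterion.
- The phenotype-label rule set is a reconstruction constrained by the
  published category totals, not a published specification; users with
  different category semantics should supply their own YAML mapping.
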