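"""Stage 4: categorize GWAS SNP-trait rows and count them per gene.

Catalog exports are filtered on the association p-value (rows strictly
over the cut are excluded) and each phenotype label is classified into
alcohol-related, liver-related or developmental disorders by an ordered
rule set — first match wins, case-insensitive.  ICD-style code prefixes
(K70, F10) precede keyword rules so that e.g. "K70 Alcoholic liver
disease" counts as alcohol-related rather than liver-related.  Rows, not
unique variants, are the counting unit: a variant associated with two
phenotypes contributes twice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import UncategorizedError, ValidationError
from .tables_io import SnpAssociationRecord

__all__ = [
    "CATEGORIES",
    "Rule",
    "CategoryMapping",
    "CategoryCounts",
    "default_mapping",
    "load_mapping",
    "filter_by_pvalue",
    "categorize_phenotype",
    "categorize_records",
    "count_categories",
]

CATEGORIES = ("alcohol", "liver", "developmental")
_MATCH_KINDS = ("prefix", "substring")


@dataclass(frozen=True)
class Rule:
    match_kind: str
    pattern: str
    category: str

    def __post_init__(self) -> None:
        if self.match_kind not in _MATCH_KINDS:
            raise ValidationError(f"unknown match kind {self.match_kind!r}")
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")

    def matches(self, label: str) -> bool:
        folded = label.casefold()
        pat = self.pattern.casefold()
        if self.match_kind == "prefix":
            return folded.startswith(pat)
        # substring matches must start at a word boundary: "alcohol" should
        # hit "Alcoholism" but "liver" must not hit "delivery"
        return re.search(r"(?<!\w)" + re.escape(pat), folded) is not None


@dataclass(frozen=True)
class CategoryMapping:
    """Ordered classification rules plus an optional fallthrough category."""

    rules: tuple[Rule, ...]
    fallthrough: str | None = None

    def __post_init__(self) -> None:
        if self.fallthrough is not None and self.fallthrough not in CATEGORIES:
            raise ValidationError(f"unknown fallthrough {self.fallthrough!r}")

    def categorize(self, label: str) -> str:
        if not label:
            raise ValidationError("empty phenotype label")
        for rule in self.rules:
            if rule.matches(label):
                return rule.category
        if self.fallthrough is None:
            raise UncategorizedError(f"no rule matches label {label!r}")
        return self.fallthrough


def _mapping_from_dict(raw: dict) -> CategoryMapping:
    rules = tuple(
        Rule(match_kind=r["match"], pattern=r["pattern"], category=r["category"])
        for r in raw.get("rules", [])
    )
    return CategoryMapping(rules=rules, fallthrough=raw.get("fallthrough"))


def load_mapping(path) -> CategoryMapping:
    """Load an ordered rule set from a YAML file.

    Format: a ``rules`` list of ``{match: prefix|substring, pattern,
    category}`` entries applied in order, and an optional ``fallthrough``
    category for rows matching no rule.
    """
    return _mapping_from_dict(yaml.safe_load(Path(path).read_text()) or {})


def default_mapping() -> CategoryMapping:
    """The packaged default rule set.

    It is the minimal ordered rule set consistent with the published
    per-category counts for both candidate genes; the file
    ``data/phenotype_categories.yaml`` can be copied and edited to
    override it.
    """
    ref = resources.files("cholscreen").joinpath("data",
                                                 "phenotype_categories.yaml")
    return _mapping_from_dict(yaml.safe_load(ref.read_text()))


def filter_by_pvalue(
    records: Iterable[SnpAssociationRecord], p_max: float = 0.05
) -> list[SnpAssociationRecord]:
    """Retain rows with p <= p_max (only strictly-over rows are excluded)."""
    if not (0.0 < p_max < 1.0):
        raise ValidationError(f"p_max must be in (0, 1), got {p_max}")
    return [r for r in records if r.p_value <= p_max]


def categorize_phenotype(label: str, mapping: CategoryMapping | None = None) -> str:
    """Category of one phenotype label under the (default) mapping."""
    mapping = mapping or default_mapping()
    return mapping.categorize(label)


def categorize_records(
    records: Iterable[SnpAssociationRecord],
    mapping: CategoryMapping | None = None,
) -> list[SnpAssociationRecord]:
    """Return copies of the records with their category assigned."""
    mapping = mapping or default_mapping()
    return [r.with_category(mapping.categorize(r.phenotype_label))
            for r in records]


@dataclass(frozen=True)
class CategoryCounts:
    """Per-category row counts for one gene's association rows."""

    gene: str
    counts: dict
    total_rows: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) > self.total_rows:
            raise ValidationError("categorized rows exceed total rows")


def count_categories(
    records: Sequence[SnpAssociationRecord], gene: str
) -> CategoryCounts:
    """Count categorized rows per category for one gene.

    Uncategorised records (category None) contribute to ``total_rows``
    but to no category bucket.
    """
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        if r.category is not None:
            if r.category not in counts:
                raise ValidationError(f"unknown category {r.category!r}")
            counts[r.category] += 1
    return CategoryCounts(gene=gene, counts=counts, total_rows=len(records))
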