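"""Stage 1 of the funnel: haplotype variability across the strain panel.

A gene is carried forward only if its parental-origin calls differ among
the panel strains — at least two distinct codes from {B6, D2, H, R}.  The
NV code marks, at the gene level, that the panel shows no variation at
all, so any NV gene is not variable by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .tables_io import HaplotypeTable

__all__ = ["HaplotypeDecision", "is_variable", "filter_by_haplotype"]


@dataclass(frozen=True)
class HaplotypeDecision:
    gene: str
    variable: bool
    distinct_calls: frozenset
    reason: str


def is_variable(calls: Sequence[str], gene: str = "") -> HaplotypeDecision:
    """Decide variability from one gene's calls across the panel.

    Variable iff at least two distinct non-NV codes appear.  Heterozygous
    (H) and recombinant (R) count as states of their own, so e.g. (H, H,
    B6, B6) is variable while a uniform row is not.  Mixing NV with
    per-strain codes violates the table invariant and raises.
    """
    if not calls:
        raise ValidationError("no haplotype calls given")
    codes = set(calls)
    if "NV" in codes:
        if codes != {"NV"}:
            raise ValidationError(
                f"gene {gene!r}: NV mixed with per-strain calls {codes - {'NV'}}"
            )
        return HaplotypeDecision(
            gene=gene, variable=False, distinct_calls=frozenset(codes),
            reason="no haplotypic variation flagged for the panel (NV)",
        )
    variable = len(codes) >= 2
    if variable:
        reason = f"{len(codes)} distinct haplotype states {sorted(codes)}"
    else:
        reason = f"uniform haplotype {next(iter(codes))!r} across the panel"
    return HaplotypeDecision(
        gene=gene, variable=variable, distinct_calls=frozenset(codes),
        reason=reason,
    )


def filter_by_haplotype(
    table: HaplotypeTable, panel: Sequence[str] | None = None
) -> tuple[list[str], dict[str, str]]:
    """Partition the gene set by variability over the panel columns.

    Returns ``(retained, removed)`` where ``removed`` maps each eliminated
    gene to its reason.  The panel defaults to every strain in the table;
    it must name at least two strains, all present in the table.
    """
    if panel is None:
        panel = table.strains
    panel = list(panel)
    for s in panel:
        if s not in table.strains:
            raise KeyError(f"panel strain {s!r} not in haplotype table")
    if len(panel) < 2:
        raise ValidationError(
            f"panel must contain at least 2 strains, got {len(panel)}"
        )
    retained: list[str] = []
    removed: dict[str, str] = {}
    for gene in table.genes:
        decision = is_variable(table.calls_for(gene, panel), gene=gene)
        if decision.variable:
            retained.append(gene)
        else:
            removed[gene] = decision.reason
    return retained, removed
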