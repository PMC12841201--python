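"""Stage 2 of the funnel: liver proteome detection and variability filters.

Genes survive this stage when (a) they are present in the proteome table,
(b) every non-missing panel abundance exceeds the background threshold
(log2 scale; 7 by default), and (c) their across-strain coefficient of
variation is non-zero.  Strains with missing abundance for a gene are
excluded gene-wise rather than failing the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateMeanError, InsufficientDataError
from .tables_io import ProteomeTable

__all__ = [
    "ProteomeDecision",
    "coefficient_of_variation",
    "round_cv",
    "filter_by_background",
    "filter_by_cv",
    "screen_proteome",
    "DEFAULT_BACKGROUND",
    "DEFAULT_CV_TOLERANCE",
]

#: Log2 abundance above which a protein counts as detected.
DEFAULT_BACKGROUND = 7.0
#: Minimum CV (%) counted as variation; effectively an exact-zero test
#: with a numerical guard.
DEFAULT_CV_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ProteomeDecision:
    """Outcome of the proteome filters for one gene.

    ``status`` is one of NO_DATA (gene absent from the table),
    BELOW_BACKGROUND, ZERO_CV, or RETAINED; ``cv_percent`` is present only
    once a CV was computable (ZERO_CV / RETAINED).
    """

    gene: str
    status: str
    cv_percent: float | None = None
    values_used: Mapping[str, float] | None = None


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * s / |mean|, with the
    sample (n-1) standard deviation.

    Full precision is returned; use :func:`round_cv` for reporting.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"CV needs at least 2 values, got {arr.size}"
        )
    mean = arr.mean()
    if mean == 0:
        raise DegenerateMeanError("CV undefined: mean is zero")
    return float(100.0 * arr.std(ddof=1) / abs(mean))


def round_cv(cv: float, decimals: int = 3) -> float:
    """Round half-away-from-zero to the reporting precision."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(cv)).quantize(q, rounding=ROUND_HALF_UP))


def filter_by_background(
    table: ProteomeTable,
    panel: Sequence[str],
    threshold: float = DEFAULT_BACKGROUND,
    genes: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, ProteomeDecision]]:
    """Keep genes detected above background in the panel strains.

    A gene is retained iff it has at least two non-missing panel values
    and every one of them is strictly above ``threshold``.  When ``genes``
    is given, candidates absent from the table are reported NO_DATA;
    otherwise all table genes are screened.

    Returns ``(retained, decisions)`` with one decision per input gene.
    """
    if genes is None:
        genes = table.genes
    retained: list[str] = []
    decisions: dict[str, ProteomeDecision] = {}
    for gene in genes:
        if not table.has_gene(gene):
            decisions[gene] = ProteomeDecision(gene=gene, status="NO_DATA")
            continue
        values = table.values_for(gene, panel)
        if len(values) < 2 or any(v <= threshold for v in values.values()):
            decisions[gene] = ProteomeDecision(
                gene=gene, status="BELOW_BACKGROUND", values_used=values
            )
            continue
        retained.append(gene)
        decisions[gene] = ProteomeDecision(
            gene=gene, status="RETAINED", values_used=values
        )
    return retained, decisions


def filter_by_cv(
    values_by_gene: Mapping[str, Mapping[str, float]],
    tolerance: float = DEFAULT_CV_TOLERANCE,
) -> tuple[list[str], dict[str, ProteomeDecision]]:
    """Keep genes whose across-strain CV exceeds ``tolerance`` percent.

    ``values_by_gene`` maps gene -> {strain: abundance} as produced by the
    background filter.  Returns ``(retained, decisions)`` where decisions
    carry the full-precision CV for every gene.
    """
    retained: list[str] = []
    decisions: dict[str, ProteomeDecision] = {}
    for gene, values in values_by_gene.items():
        cv = coefficient_of_variation(list(values.values()))
        if cv > tolerance:
            retained.append(gene)
            decisions[gene] = ProteomeDecision(
                gene=gene, status="RETAINED", cv_percent=cv, values_used=values
            )
        else:
            decisions[gene] = ProteomeDecision(
                gene=gene, status="ZERO_CV", cv_percent=cv, values_used=values
            )
    return retained, decisions


def screen_proteome(
    table: ProteomeTable,
    genes: Sequence[str],
    panel: Sequence[str],
    threshold: float = DEFAULT_BACKGROUND,
    tolerance: float = DEFAULT_CV_TOLERANCE,
) -> tuple[list[str], dict[str, ProteomeDecision], dict[str, ProteomeDecision]]:
    """Run the background filter then the CV filter over candidate genes.

    Returns ``(retained, background_decisions, cv_decisions)``.
    """
    above, bg_decisions = filter_by_background(table, panel, threshold, genes)
    values_by_gene = {g: bg_decisions[g].values_used for g in above}
    retained, cv_decisions = filter_by_cv(values_by_gene, tolerance)
    return retained, bg_decisions, cv_decisions
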