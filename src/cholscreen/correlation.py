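"""Stage 3 of the funnel: strain-level protein-phenotype correlation.

For every surviving gene, protein abundance across the panel strains is
correlated (Pearson) with the percent statistic in each of the four
conditions — two brain regions x two choline doses.  A gene is selected
when at least ``min_conditions`` of the ``n_conditions`` coefficients
exceed ``r_threshold`` (signed by default; an absolute-value mode covers
screens that treat strong negative trends as equally interesting).

With only a handful of strains the p-values are severely underpowered;
they are reported for information and never used for selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig
from .errors import DegenerateVarianceError, InsufficientStrainsError
from .reduction import ReductionMatrix
from .tables_io import ProteomeTable

__all__ = [
    "CorrelationCell",
    "pearson_r",
    "correlation_pvalue",
    "screen_correlations",
    "select_from_grid",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationCell:
    """One gene x (region, dose) correlation result."""

    gene: str
    region: str
    dose: float
    r: float
    n: int
    p: float | None = None


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Raises :class:`DegenerateVarianceError` when either variable has zero
    variance (duplicated values are fine as long as some spread remains).
    The result is clipped to [-1, 1] against floating-point overshoot.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InsufficientStrainsError(
            f"correlation needs at least 3 points, got {x.size}"
        )
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        which = "x" if sxx == 0.0 else "y"
        raise DegenerateVarianceError(f"zero variance in {which}")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson coefficient from n points.

    Uses ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
    freedom.  ``|r| = 1`` returns 0 with a logged note (the t statistic
    diverges).
    """
    if n < 3:
        raise InsufficientStrainsError(f"p-value needs n >= 3, got {n}")
    if abs(r) >= 1.0:
        log.info("correlation |r| = 1 with n = %d: p reported as 0", n)
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _passes(r: float, cfg: ScreenConfig) -> bool:
    v = abs(r) if cfg.use_absolute_r else r
    return bool(v > cfg.r_threshold)  # strict: exactly-at-threshold fails


def select_from_grid(grid: pd.DataFrame, cfg: ScreenConfig) -> list[str]:
    """Apply the min-of-n selection rule to a precomputed r grid.

    ``grid`` has genes as rows and one column per condition; NaN cells do
    not count toward the passing tally.
    """
    selected = []
    for gene, row in grid.iterrows():
        passing = sum(
            _passes(float(r), cfg) for r in row if not np.isnan(float(r))
        )
        if passing >= cfg.min_conditions:
            selected.append(gene)
    return selected


def screen_correlations(
    proteome: ProteomeTable,
    reductions: ReductionMatrix,
    genes: Sequence[str],
    cfg: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, list[CorrelationCell], list[str]]:
    """Correlate protein abundance with the percent statistic per condition.

    For each gene and each (region, dose) condition, the strains used are
    those with both a non-missing abundance and a non-missing matrix cell
    (strains lacking either are dropped with a logged reason); at least 3
    common strains are required.

    Returns ``(grid, cells, selected)``: the r grid (genes x conditions),
    the full per-cell results including n and the informational p-value,
    and the genes passing the selection rule.
    """
    cfg = cfg or ScreenConfig()
    conditions = reductions.conditions
    grid = pd.DataFrame(np.nan, index=list(genes),
                        columns=pd.MultiIndex.from_tuples(
                            conditions, names=["region", "dose"]))
    cells: list[CorrelationCell] = []
    for gene in genes:
        abundances = proteome.values_for(gene, panel=cfg.panel)
        for region, dose in conditions:
            common = [
                s for s, v in abundances.items()
                if s in reductions.strains
                and not np.isnan(reductions.value(s, region, dose))
            ]
            skipped = sorted(set(abundances) - set(common))
            if skipped:
                log.info(
                    "gene %s, %s/%s: strains %s lack phenotype values",
                    gene, region, dose, skipped,
                )
            if len(common) < 3:
                raise InsufficientStrainsError(
                    f"gene {gene!r}, condition ({region}, {dose}): only"
                    f" {len(common)} strains have both protein and"
                    " phenotype values"
                )
            x = [abundances[s] for s in common]
            y = [reductions.value(s, region, dose) for s in common]
            r = pearson_r(x, y)
            cells.append(CorrelationCell(
                gene=gene, region=region, dose=dose, r=r, n=len(common),
                p=correlation_pvalue(r, len(common)),
            ))
            grid.at[gene, (region, dose)] = r
    return grid, cells, select_from_grid(grid, cfg)
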