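"""Percent reduction in ethanol-induced cell death.

Litter-mean observations are aggregated to strain means (the litter is the
unit of analysis), maltose/dextrin controls are pooled across choline
doses, and each choline-treated ethanol group is normalised against the
ethanol-only baseline:

    rho = (CE - MD) / (E0 - MD)

where CE is the choline+ethanol strain mean, E0 the ethanol-without-choline
mean and MD the pooled control mean.  ``100 * rho`` is the percentage of
ethanol-induced cell death REMAINING under choline; ``100 * (1 - rho)`` is
the percentage REDUCTION.  Both conventions are supported and every output
records which one it carries; values are never clamped to [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDenominatorError, MissingGroupError
from .tables_io import CellDeathObservation, REGIONS

__all__ = [
    "Convention",
    "StrainConditionMean",
    "ReductionMatrix",
    "litter_to_strain_means",
    "pool_controls",
    "percent_reduction",
    "build_reduction_matrix",
]

log = logging.getLogger(__name__)

#: Choline doses at which the reduction statistic is defined.
TREATED_DOSES = (100.0, 250.0)


class Convention(str, Enum):
    """Sign convention of the percent statistic.

    REMAINING is the formula exactly as published (``100 * rho``);
    REDUCTION is its complement (``100 * (1 - rho)``).
    """

    REMAINING = "REMAINING"
    REDUCTION = "REDUCTION"


@dataclass(frozen=True)
class StrainConditionMean:
    """Arithmetic mean of the litter means in one treatment group."""

    strain: str
    region: str
    treatment: str
    choline_dose: float
    mean_cell_death: float
    n_litters: int


def litter_to_strain_means(
    obs: Sequence[CellDeathObservation],
) -> list[StrainConditionMean]:
    """Aggregate litter means to one mean per (strain, region, treatment,
    dose) group, in first-appearance order of the groups."""
    if not obs:
        raise ValueError("no observations")
    groups: dict[tuple, list[float]] = {}
    for o in obs:
        key = (o.strain, o.region, o.treatment, o.choline_dose)
        groups.setdefault(key, []).append(o.litter_mean)
    return [
        StrainConditionMean(
            strain=k[0], region=k[1], treatment=k[2], choline_dose=k[3],
            mean_cell_death=float(np.mean(v)), n_litters=len(v),
        )
        for k, v in groups.items()
    ]


def pool_controls(
    means: Iterable[StrainConditionMean], strain: str, region: str
) -> float:
    """Litter-weighted mean over all maltose/dextrin groups of a strain and
    region, regardless of choline dose.

    The controls (with and without choline) are pooled unconditionally.
    Weighting by litter count keeps the litter, not the group, as the unit
    of analysis.
    """
    md = [m for m in means
          if m.strain == strain and m.region == region and m.treatment == "MD"]
    if not md:
        raise MissingGroupError(
            f"no maltose/dextrin control data for strain {strain!r},"
            f" region {region!r}"
        )
    total = sum(m.n_litters for m in md)
    return sum(m.mean_cell_death * m.n_litters for m in md) / total


def percent_reduction(
    ce: float, e0: float, md: float,
    convention: Convention = Convention.REMAINING,
) -> float:
    """The percent statistic for one (strain, region, dose) cell.

    Parameters
    ----------
    ce : choline + ethanol strain mean.
    e0 : ethanol without choline strain mean.
    md : pooled maltose/dextrin control mean.
    convention : REMAINING returns ``100 * rho``; REDUCTION returns
        ``100 * (1 - rho)`` with ``rho = (ce - md) / (e0 - md)``.

    Raises
    ------
    DegenerateDenominatorError
        If ``e0 == md`` — no ethanol-induced cell death to normalise by.
    """
    if e0 == md:
        raise DegenerateDenominatorError(
            "ethanol-only mean equals control mean: no ethanol-induced"
            " cell death"
        )
    rho = (ce - md) / (e0 - md)
    convention = Convention(convention)
    if convention is Convention.REMAINING:
        return 100.0 * rho
    return 100.0 * (1.0 - rho)


@dataclass
class ReductionMatrix:
    """Strain x (region, dose) percent values under a stated convention.

    ``values`` has strains as rows and a (region, dose) MultiIndex on the
    columns; cells for which a required group was missing are NaN and the
    reason is kept in ``dropped``.
    """

    values: pd.DataFrame
    convention: Convention
    dropped: list[tuple[str, str, float, str]] = field(default_factory=list)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[tuple[str, float]]:
        return list(self.values.columns)

    def value(self, strain: str, region: str, dose: float) -> float:
        return float(self.values.at[strain, (region, dose)])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = [f"{r}_{int(d)}" for r, d in out.columns]
        out.index.name = "strain"
        out.to_csv(path, sep="\t")


def build_reduction_matrix(
    obs: Sequence[CellDeathObservation],
    convention: Convention = Convention.REMAINING,
    regions: Sequence[str] = REGIONS,
    doses: Sequence[float] = TREATED_DOSES,
) -> ReductionMatrix:
    """Compute the percent matrix over every strain, region and treated dose.

    Strains lacking a required group (pooled controls, ethanol-only
    baseline, or the treated group itself) get NaN in the affected cells;
    each omission is logged and recorded in ``dropped``.
    """
    means = litter_to_strain_means(obs)
    strains = list(dict.fromkeys(o.strain for o in obs))
    by_group = {
        (m.strain, m.region, m.treatment, m.choline_dose): m for m in means
    }
    columns = pd.MultiIndex.from_tuples(
        [(r, d) for r in regions for d in doses], names=["region", "dose"]
    )
    values = pd.DataFrame(np.nan, index=strains, columns=columns)
    dropped: list[tuple[str, str, float, str]] = []

    def drop(strain, region, dose, reason):
        dropped.append((strain, region, dose, reason))
        log.info("dropping %s/%s/%s: %s", strain, region, dose, reason)

    for strain in strains:
        for region in regions:
            try:
                md = pool_controls(means, strain, region)
            except MissingGroupError as exc:
                for dose in doses:
                    drop(strain, region, dose, str(exc))
                continue
            e0 = by_group.get((strain, region, "ETOH", 0.0))
            if e0 is None:
                for dose in doses:
                    drop(strain, region, dose, "no ethanol-without-choline group")
                continue
            for dose in doses:
                ce = by_group.get((strain, region, "ETOH", dose))
                if ce is None:
                    drop(strain, region, dose,
                         f"no ethanol group at dose {dose}")
                    continue
                try:
                    values.at[strain, (region, dose)] = percent_reduction(
                        ce.mean_cell_death, e0.mean_cell_death, md, convention
                    )
                except DegenerateDenominatorError as exc:
                    raise DegenerateDenominatorError(
                        f"strain {strain!r}, region {region!r}: {exc}"
                    ) from exc
    return ReductionMatrix(values=values, convention=Convention(convention),
                           dropped=dropped)
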