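"""Synthetic strain-panel generator with a planted protein-phenotype link.

The generator emulates the statistical structure of the real inputs: a
gene x strain haplotype-call table, a log2-scale liver proteome with
per-gene missingness and optionally whole strains without proteome data,
litter-level cell-death observations under the two-treatment
three-dose design, and GWAS association rows drawn from per-category
label pools.

Planted genes carry a linear link: the choline+ethanol group mean moves
with the strain's protein abundance so that the expected percent
reduction in ethanol-induced cell death is

    reduction% = 100 * (1 - rho0) + beta_region * (x - x_bar)

where ``x`` is the strain's log2 abundance of the planted gene and
``rho0`` the baseline remaining fraction.  Non-planted genes have no
systematic link, so a correct screen should recover exactly the planted,
haplotype-variable, above-background genes when noise is small.

Every generator is a pure function of (params, seed): the seed lives on
the params object and fixed params always reproduce the same tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables_io import (CellDeathObservation, HaplotypeTable, ProteomeTable,
                        REGIONS, SnpAssociationRecord)

__all__ = ["PlantedGene", "SimulationParams", "simulate_panel",
           "simulate_celldeath", "simulate_gwas"]

_PARENTAL = ("B6", "D2")

#: Phenotype labels per category, mirroring the label styles of public
#: GWAS catalog exports (ICD-coded and free-text).  Every label
#: categorizes correctly under the packaged default rule set.
LABEL_POOLS = {
    "alcohol": (
        "K70 Alcoholic liver disease",
        "F10 Mental and behavioral disorders due to use of alcohol",
        "Alcoholism",
        "alcohol-related disorders",
    ),
    "liver": (
        "gamma glutamyltransferase activity",
        "Total cholesterol levels",
        "Triglyceride levels",
        "Disorders of lipid metabolism",
    ),
    "developmental": (
        "height",
        "Lack of normal physiological development",
        "schizophrenia",
        "Dementia with cerebral degenerations",
    ),
}


@dataclass(frozen=True)
class PlantedGene:
    """A gene given a linear protein-to-phenotype link.

    Slopes are in reduction-percent per log2 abundance unit and are set
    independently per brain region so a gene can pass in one region and
    not the other, exercising the min-of-n selection rule.
    """

    gene: str
    beta_brainstem: float = 50.0
    beta_forebrain: float = 35.0

    def beta(self, region: str) -> float:
        return self.beta_brainstem if region == "brainstem" else self.beta_forebrain


@dataclass
class SimulationParams:
    """Generator settings; defaults mirror the study design.

    Four strains, 22 candidate genes of which roughly half vary in
    haplotype, one strain without proteome data, and 5-8 litters per
    treatment group.  ``noise_sd`` is the litter-level cell-death noise
    (arbitrary staining units); with the default control mean 20 and
    ethanol effect +20, ``beta_brainstem = 50`` and a strain protein
    spread of 0.3 give a planted reduction-percent signal roughly three
    times the aggregation noise.
    """

    n_strains: int = 4
    n_genes: int = 22
    p_variable: float = 12 / 22
    p_het: float = 0.05
    p_recomb: float = 0.05
    p_nv: float = 0.7            # share of non-variable genes flagged NV
    proteome_mean: float = 16.0  # log2 scale
    gene_sd: float = 2.0         # across-gene spread of mean abundance
    strain_sd: float = 0.3       # across-strain spread within a gene
    p_gene_missing: float = 0.3  # gene absent from the proteome table
    n_missing_strains: int = 1   # strains with no proteome data at all
    planted_genes: tuple[PlantedGene, ...] = (PlantedGene("planted1"),)
    base_remaining: float = 0.4  # rho0: remaining fraction without a link
    baseline_md: float = 20.0    # control group mean, cell-death units
    ethanol_effect: float = 20.0 # ethanol-only shift over control
    noise_sd: float = 2.0        # litter-mean noise, cell-death units
    litters_min: int = 5
    litters_max: int = 8
    n_gwas_rows: int = 100
    fraction_above_p_max: float = 0.2
    p_cut: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_variable", "p_het", "p_recomb", "p_nv",
                     "p_gene_missing", "fraction_above_p_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.litters_min < 1 or self.litters_max < self.litters_min:
            raise ValueError("need 1 <= litters_min <= litters_max")
        if self.ethanol_effect == 0:
            raise ValueError("ethanol_effect must be nonzero")
        if self.n_strains - self.n_missing_strains < 3:
            raise ValueError(
                "need at least 3 strains with proteome data for the"
                " correlation stage"
            )
        if len(self.planted_genes) > self.n_genes:
            raise ValueError("more planted genes than genes")

    # independent child streams so each generator is reproducible on its own
    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _strain_names(n: int) -> list[str]:
    return [f"BXD{i + 1:02d}" for i in range(n)]


def _gene_names(params: SimulationParams) -> list[str]:
    planted = [p.gene for p in params.planted_genes]
    fillers = [f"gene{i + 1:03d}" for i in range(params.n_genes - len(planted))]
    return planted + fillers


def simulate_panel(
    params: SimulationParams,
) -> tuple[HaplotypeTable, ProteomeTable, dict]:
    """Draw the haplotype and proteome tables plus a ground-truth record.

    Planted genes are variable, present in the proteome and above
    background by construction; other genes vary with probability
    ``p_variable`` and are absent from the proteome with probability
    ``p_gene_missing``.  The last ``n_missing_strains`` strains have no
    proteome data (all cells missing), emulating panel members absent
    from the reference dataset.
    """
    rng = params._rng(0)
    strains = _strain_names(params.n_strains)
    genes = _gene_names(params)
    planted = {p.gene for p in params.planted_genes}

    calls = {}
    variable_genes = []
    for gene in genes:
        if gene in planted or rng.random() < params.p_variable:
            row = []
            for _ in strains:
                u = rng.random()
                if u < params.p_het:
                    row.append("H")
                elif u < params.p_het + params.p_recomb:
                    row.append("R")
                else:
                    row.append(_PARENTAL[rng.integers(2)])
            if len(set(row)) < 2:  # force the promised variability
                i = rng.integers(len(row))
                row[i] = "D2" if row[i] != "D2" else "B6"
            variable_genes.append(gene)
        elif rng.random() < params.p_nv:
            row = ["NV"] * len(strains)
        else:
            row = [_PARENTAL[rng.integers(2)]] * len(strains)
        calls[gene] = row
    hap_frame = pd.DataFrame.from_dict(calls, orient="index", columns=strains)
    hap_frame.index.name = "gene"

    present_genes = []
    abundances = {}
    for gene in genes:
        if gene not in planted and rng.random() < params.p_gene_missing:
            continue
        mean = params.proteome_mean + rng.normal(0.0, params.gene_sd)
        if gene in planted:
            mean = max(mean, 10.0)  # keep planted genes clear of background
        abundances[gene] = mean + rng.normal(0.0, params.strain_sd,
                                             len(strains))
        present_genes.append(gene)
    prot_frame = pd.DataFrame.from_dict(abundances, orient="index",
                                        columns=strains, dtype=float)
    prot_frame.index.name = "gene"
    missing_strains = strains[len(strains) - params.n_missing_strains:] \
        if params.n_missing_strains else []
    for s in missing_strains:
        prot_frame[s] = np.nan

    truth = {
        "planted": sorted(planted),
        "variable": variable_genes,
        "proteome_present": present_genes,
        "missing_strains": missing_strains,
        "strains": strains,
    }
    return HaplotypeTable(hap_frame), ProteomeTable(prot_frame), truth


def expected_reduction_percent(
    params: SimulationParams, proteome: ProteomeTable, strain: str, region: str
) -> float:
    """Noise-free reduction percent for one strain and region.

    Baseline ``100 * (1 - rho0)`` shifted by each planted gene's slope
    times the strain's centred log2 abundance; strains without proteome
    data sit at the baseline.
    """
    pct = 100.0 * (1.0 - params.base_remaining)
    for pg in params.planted_genes:
        values = proteome.values_for(pg.gene)
        if strain not in values:
            continue
        center = float(np.mean(list(values.values())))
        pct += pg.beta(region) * (values[strain] - center)
    return pct


def simulate_celldeath(
    params: SimulationParams, proteome: ProteomeTable
) -> list[CellDeathObservation]:
    """Draw litter-level observations for the full two-treatment design.

    Per strain, region and choline dose in {0, 100, 250} mg/kg there is a
    maltose/dextrin control group (mean ``baseline_md``) and an ethanol
    group; ethanol without choline sits at ``baseline_md +
    ethanol_effect`` and choline+ethanol groups at the mean implied by
    the strain's expected reduction percent.  Litter counts are uniform
    on [litters_min, litters_max]; litter means are normal with
    ``noise_sd`` and floored at zero.
    """
    for pg in params.planted_genes:
        if not proteome.has_gene(pg.gene):
            raise KeyError(f"planted gene {pg.gene!r} not in proteome table")
    rng = params._rng(1)
    strains = proteome.strains
    obs: list[CellDeathObservation] = []
    doses = (0.0, 100.0, 250.0)
    for strain in strains:
        for region in REGIONS:
            reduction = expected_reduction_percent(params, proteome, strain,
                                                   region)
            rho = 1.0 - reduction / 100.0
            group_means = {("MD", d): params.baseline_md for d in doses}
            group_means[("ETOH", 0.0)] = (params.baseline_md
                                          + params.ethanol_effect)
            for d in (100.0, 250.0):
                group_means[("ETOH", d)] = (params.baseline_md
                                            + rho * params.ethanol_effect)
            for (treatment, dose), mean in group_means.items():
                n = int(rng.integers(params.litters_min,
                                     params.litters_max + 1))
                litters = np.maximum(
                    0.0, mean + rng.normal(0.0, params.noise_sd, n)
                ) if params.noise_sd > 0 else np.full(n, mean)
                for j, lm in enumerate(litters):
                    obs.append(CellDeathObservation(
                        strain=strain, region=region, treatment=treatment,
                        choline_dose=dose, litter_id=f"L{j + 1}",
                        litter_mean=float(lm),
                    ))
    return obs


def simulate_gwas(
    params: SimulationParams,
    category_weights: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    n_rows: int | None = None,
) -> list[SnpAssociationRecord]:
    """Draw uncategorised association rows.

    Categories are drawn with ``category_weights`` (alcohol, liver,
    developmental; must sum to 1), labels uniformly from the per-category
    pools.  A fraction ``fraction_above_p_max`` of rows get p-values
    above the cut (uniform on (p_cut, 0.5]); the rest are log-uniform on
    [1e-8, p_cut].
    """
    weights = np.asarray(category_weights, dtype=float)
    if weights.size != 3 or not np.isclose(weights.sum(), 1.0):
        raise ValueError("category_weights must be 3 probabilities summing to 1")
    rng = params._rng(2)
    n_rows = params.n_gwas_rows if n_rows is None else n_rows
    categories = list(LABEL_POOLS)
    records = []
    for _ in range(n_rows):
        cat = categories[rng.choice(3, p=weights)]
        pool = LABEL_POOLS[cat]
        label = pool[rng.integers(len(pool))]
        if rng.random() < params.fraction_above_p_max:
            p = float(rng.uniform(np.nextafter(params.p_cut, 1.0), 0.5))
        else:
            p = float(10.0 ** rng.uniform(-8.0, np.log10(params.p_cut)))
        records.append(SnpAssociationRecord(
            variant_id=f"rs{rng.integers(10**6, 10**8)}",
            phenotype_label=label, p_value=p,
        ))
    return records
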