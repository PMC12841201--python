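"""End-to-end orchestration of the screening funnel.

Stages run strictly in order: haplotype variability -> proteome
background -> proteome CV -> protein-phenotype correlation -> SNP
annotation of the survivors.  Every elimination is recorded with its
stage and reason; a stage failure aborts the run but preserves the
partial report.

The correlation stage accepts either litter-level cell-death
observations (the percent matrix is computed internally) or a
precomputed Pearson-r grid.  The grid route exists because published
screens often print the correlation grid without the underlying
phenotype values; the two routes select identically whenever the grid
equals the computed coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .correlation import screen_correlations, select_from_grid
from .errors import PipelineStageError
from .haplotype import filter_by_haplotype
from .proteome import screen_proteome
from .reduction import ReductionMatrix, build_reduction_matrix
from .report import FunnelReport, StageResult, write_funnel_report
from .snp import (categorize_records, count_categories, default_mapping,
                  filter_by_pvalue)
from .tables_io import (HaplotypeTable, ProteomeTable, SnpAssociationRecord,
                        read_celldeath_table, read_gwas_table,
                        read_haplotype_table, read_proteome_table)

__all__ = ["PipelineRunSpec", "run_funnel", "run_funnel_tables"]

log = logging.getLogger(__name__)


@dataclass
class PipelineRunSpec:
    """File-level inputs for one funnel run.

    Exactly one of ``celldeath_path`` (litter observations) or
    ``correlations_path`` (precomputed r grid) feeds the correlation
    stage.  ``gwas_paths`` maps gene symbol -> association table path.
    """

    haplotype_path: str | Path
    proteome_path: str | Path
    celldeath_path: str | Path | None = None
    correlations_path: str | Path | None = None
    gwas_paths: Mapping[str, str | Path] = field(default_factory=dict)
    config: ScreenConfig = field(default_factory=ScreenConfig)
    out_dir: str | Path | None = None

    def validate(self) -> None:
        if (self.celldeath_path is None) == (self.correlations_path is None):
            raise ValueError(
                "exactly one of celldeath_path or correlations_path required"
            )
        for p in [self.haplotype_path, self.proteome_path,
                  self.celldeath_path, self.correlations_path,
                  *self.gwas_paths.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _read_grid(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    cols = []
    for c in frame.columns:
        region, dose = c.rsplit("_", 1)
        cols.append((region, int(dose)))
    frame.columns = pd.MultiIndex.from_tuples(cols, names=["region", "dose"])
    return frame


def _grid_lookup(grid: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Restrict a correlation grid to ``genes``, case-insensitively."""
    folded = {str(g).casefold(): g for g in grid.index}
    rows = []
    for g in genes:
        key = str(g).casefold()
        if key not in folded:
            raise KeyError(f"gene {g!r} missing from the correlation grid")
        rows.append(folded[key])
    out = grid.loc[rows]
    out.index = list(genes)
    return out


def run_funnel_tables(
    haplotypes: HaplotypeTable,
    proteome: ProteomeTable,
    *,
    reductions: ReductionMatrix | None = None,
    correlation_grid: pd.DataFrame | None = None,
    snp_tables: Mapping[str, Sequence[SnpAssociationRecord]] | None = None,
    config: ScreenConfig | None = None,
    mapping=None,
) -> FunnelReport:
    """Run the funnel on in-memory tables; see module docstring for order."""
    cfg = config or ScreenConfig()
    if (reductions is None) == (correlation_grid is None):
        raise ValueError(
            "exactly one of reductions or correlation_grid required"
        )
    report = FunnelReport(config=cfg.to_dict())
    stage = "haplotype_variability"
    try:
        panel = list(cfg.panel) if cfg.panel else haplotypes.strains
        retained, removed = filter_by_haplotype(haplotypes, panel)
        report.stages.append(StageResult(
            name=stage,
            criterion=("at least 2 distinct haplotype states among panel"
                       f" strains {panel}"),
            retained=retained, removed=removed,
        ))
        for g, reason in removed.items():
            log.info("eliminated %s at %s: %s", g, stage, reason)

        stage = "proteome_screen"
        prot_panel = [s for s in panel if s in proteome.strains]
        survivors, bg_dec, cv_dec = screen_proteome(
            proteome, retained, prot_panel,
            threshold=cfg.background_threshold, tolerance=cfg.cv_tolerance,
        )
        bg_removed = {
            g: f"{d.status}: no proteome data" if d.status == "NO_DATA"
            else f"{d.status}: abundance not above {cfg.background_threshold}"
            for g, d in bg_dec.items() if d.status != "RETAINED"
        }
        bg_retained = [g for g in retained if g not in bg_removed]
        report.stages.append(StageResult(
            name="proteome_background",
            criterion=("proteome data present and every panel abundance"
                       f" strictly above {cfg.background_threshold} (log2)"),
            retained=bg_retained, removed=bg_removed,
        ))
        cv_removed = {
            g: (f"ZERO_CV: coefficient of variation"
                f" {d.cv_percent:.3f}% <= {cfg.cv_tolerance}")
            for g, d in cv_dec.items() if d.status != "RETAINED"
        }
        cv_retained = [g for g in bg_retained if g not in cv_removed]
        report.stages.append(StageResult(
            name="proteome_cv",
            criterion=("across-strain coefficient of variation above"
                       f" {cfg.cv_tolerance}%"),
            retained=cv_retained, removed=cv_removed,
        ))
        for g in {**bg_removed, **cv_removed}:
            log.info("eliminated %s at proteome screen", g)

        stage = "correlation_screen"
        if correlation_grid is not None:
            grid = _grid_lookup(correlation_grid, cv_retained)
            selected = select_from_grid(grid, cfg)
        else:
            grid, _cells, selected = screen_correlations(
                proteome, reductions, cv_retained, cfg
            )
        comparator = "|r|" if cfg.use_absolute_r else "r"
        corr_removed = {}
        for g in cv_retained:
            if g not in selected:
                row = grid.loc[g]
                passing = int(sum(
                    (abs(v) if cfg.use_absolute_r else v) > cfg.r_threshold
                    for v in row if not np.isnan(float(v))
                ))
                corr_removed[g] = (
                    f"only {passing} of {len(row)} conditions with"
                    f" {comparator} > {cfg.r_threshold}"
                )
        report.stages.append(StageResult(
            name=stage,
            criterion=(f"at least {cfg.min_conditions} of"
                       f" {cfg.n_conditions} conditions with {comparator} >"
                       f" {cfg.r_threshold}"),
            retained=list(selected), removed=corr_removed,
        ))
        for g, reason in corr_removed.items():
            log.info("eliminated %s at %s: %s", g, stage, reason)

        stage = "snp_annotation"
        mapping = mapping or default_mapping()
        for gene in selected:
            records = (snp_tables or {}).get(gene)
            if records is None:
                continue
            kept = filter_by_pvalue(records, cfg.p_max)
            counts = count_categories(categorize_records(kept, mapping), gene)
            report.annotations[gene] = {
                "snp_counts": counts.counts,
                "rows_considered": len(records),
                "rows_after_p_filter": counts.total_rows,
            }
        report.stages.append(StageResult(
            name=stage,
            criterion=(f"association rows with p <= {cfg.p_max} counted per"
                       " category (annotation only, no elimination)"),
            retained=list(selected), removed={},
        ))
        report.final_candidates = list(selected)
    except Exception as exc:
        report.stages.append(StageResult(
            name=stage, criterion="", retained=[], removed={},
            status="ABORTED",
        ))
        raise PipelineStageError(stage, exc, report) from exc
    report.validate()
    return report


def run_funnel(spec: PipelineRunSpec) -> FunnelReport:
    """Run the funnel from files per the run spec.

    When ``out_dir`` is set, the report is written there in all three
    formats together with the per-stage gene lists.
    """
    spec.validate()
    haplotypes = read_haplotype_table(spec.haplotype_path)
    proteome = read_proteome_table(spec.proteome_path)
    reductions = None
    grid = None
    if spec.celldeath_path is not None:
        obs = read_celldeath_table(spec.celldeath_path)
        reductions = build_reduction_matrix(obs, spec.config.convention)
    else:
        grid = _read_grid(spec.correlations_path)
    snp_tables = {g: read_gwas_table(p) for g, p in spec.gwas_paths.items()}
    report = run_funnel_tables(
        haplotypes, proteome, reductions=reductions, correlation_grid=grid,
        snp_tables=snp_tables, config=spec.config,
    )
    if spec.out_dir is not None:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_funnel_report(report, out / "funnel_report.tsv", "tsv")
        write_funnel_report(report, out / "funnel_report.json", "json")
        write_funnel_report(report, out / "funnel_report.md", "markdown")
        if reductions is not None:
            reductions.to_tsv(out / "reduction_matrix.tsv")
    return report
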