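"""Readers, validators and bundled fixtures for the four tabular inputs.

The screen consumes four kinds of tables:

* gene x strain haplotype calls (codes ``B6``/``D2``/``H``/``R``/``NV``),
* gene x strain liver protein abundance on a log2 scale (``n/a`` = missing),
* litter-level cell-death observations (strain, brain region, treatment,
  choline dose, litter id, litter mean),
* SNP-trait association rows (variant id, phenotype label, p-value).

All readers accept UTF-8 TSV (default) or CSV with a header row, a period
decimal separator and ``n/a``/empty for missing.  The transcriptions of the
published strain-panel tables ship with the package and are exposed through
``load_study_tables`` and the individual ``load_*`` helpers.
"""

from __future__ import annotations

import re
from collections import namedtuple
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "HAPLOTYPE_CODES",
    "REGIONS",
    "TREATMENTS",
    "HaplotypeTable",
    "ProteomeTable",
    "CellDeathObservation",
    "SnpAssociationRecord",
    "normalize_scientific",
    "read_haplotype_table",
    "read_proteome_table",
    "read_celldeath_table",
    "read_gwas_table",
    "write_celldeath_table",
    "load_haplotype_calls",
    "load_liver_proteome",
    "load_correlation_grid",
    "load_snp_associations",
    "load_study_tables",
]

HAPLOTYPE_CODES = frozenset({"B6", "D2", "H", "R", "NV"})
REGIONS = ("forebrain", "brainstem")
TREATMENTS = ("ETOH", "MD")

#: Tokens treated as a missing abundance cell (case-insensitive).
MISSING_TOKENS = frozenset({"n/a", ""})

_SEP = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _SEP[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# domain containers


class _GeneIndexed:
    """Case-insensitive gene lookup over a genes x strains frame."""

    frame: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def strains(self) -> list[str]:
        return list(self.frame.columns)

    def _resolve_gene(self, gene: str) -> str:
        if gene in self.frame.index:
            return gene
        folded = gene.casefold()
        for g in self.frame.index:
            if g.casefold() == folded:
                return g
        raise KeyError(f"gene {gene!r} not in table")

    def has_gene(self, gene: str) -> bool:
        try:
            self._resolve_gene(gene)
            return True
        except KeyError:
            return False


@dataclass
class HaplotypeTable(_GeneIndexed):
    """Gene x strain parental-origin calls for a recombinant-inbred panel.

    Calls are one of ``B6``/``D2`` (parental haplotype), ``H``
    (heterozygous), ``R`` (recombinant) or ``NV`` (no variation across the
    panel; a gene-level flag, so an NV gene is NV in every strain column).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol {dup!r}")
        if self.frame.columns.duplicated().any():
            dup = self.frame.columns[self.frame.columns.duplicated()][0]
            raise ValidationError(f"duplicate strain id {dup!r}")
        for gene, row in self.frame.iterrows():
            for strain, code in row.items():
                if code not in HAPLOTYPE_CODES:
                    raise ValidationError(
                        f"unknown haplotype code {code!r} for gene {gene!r},"
                        f" strain {strain!r}"
                    )
            codes = set(row)
            if "NV" in codes and codes != {"NV"}:
                raise ValidationError(
                    f"gene {gene!r} mixes NV with per-strain calls; NV is a"
                    " gene-level flag and must fill the whole row"
                )

    def call(self, gene: str, strain: str) -> str:
        return self.frame.at[self._resolve_gene(gene), strain]

    def calls_for(self, gene: str, panel: Sequence[str] | None = None) -> list[str]:
        row = self.frame.loc[self._resolve_gene(gene)]
        if panel is None:
            return list(row)
        for s in panel:
            if s not in self.frame.columns:
                raise KeyError(f"strain {s!r} not in haplotype table")
        return [row[s] for s in panel]


@dataclass
class ProteomeTable(_GeneIndexed):
    """Gene x strain liver protein abundance on a log2 scale.

    A difference of 1.0 corresponds to a two-fold expression change.
    Missing cells are NaN; a gene may also be entirely absent from the
    table, which is distinct from present-with-missing-cells.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol {dup!r}")
        if self.frame.columns.duplicated().any():
            dup = self.frame.columns[self.frame.columns.duplicated()][0]
            raise ValidationError(f"duplicate strain id {dup!r}")
        values = self.frame.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise ValidationError("abundance values must be finite where present")

    def abundance(self, gene: str, strain: str) -> float:
        """Abundance for one cell; NaN when missing."""
        return float(self.frame.at[self._resolve_gene(gene), strain])

    def values_for(
        self, gene: str, panel: Sequence[str] | None = None
    ) -> dict[str, float]:
        """Non-missing abundances for a gene, restricted to ``panel``."""
        row = self.frame.loc[self._resolve_gene(gene)]
        strains = list(row.index) if panel is None else list(panel)
        out = {}
        for s in strains:
            if s not in row.index:
                raise KeyError(f"strain {s!r} not in proteome table")
            v = float(row[s])
            if not np.isnan(v):
                out[s] = v
        return out


@dataclass(frozen=True)
class CellDeathObservation:
    """One litter-mean cell-death measurement.

    ``treatment`` is ``ETOH`` (ethanol) or ``MD`` (isocaloric
    maltose/dextrin control); ``choline_dose`` is mg/kg; ``litter_mean`` is
    the mean cell-death level over the embryos of one litter, in arbitrary
    staining units.
    """

    strain: str
    region: str
    treatment: str
    choline_dose: float
    litter_id: str
    litter_mean: float

    def key(self) -> tuple:
        return (self.strain, self.region, self.treatment, self.choline_dose,
                self.litter_id)


@dataclass(frozen=True)
class SnpAssociationRecord:
    """One SNP-trait association row from a GWAS catalog export.

    ``category`` is assigned by the categorizer; ``None`` means unassigned.
    """

    variant_id: str
    phenotype_label: str
    p_value: float
    category: str | None = None

    def with_category(self, category: str) -> "SnpAssociationRecord":
        return replace(self, category=category)


# ---------------------------------------------------------------------------
# scientific-notation pre-pass

_SCI_RE = re.compile(r"\s*[x×]\s*10\s*\^?\s*([+-]?\d+)\s*\^?", re.IGNORECASE)


def normalize_scientific(text: str) -> str:
    """Normalise published numeric notation to plain ASCII ``e`` notation.

    Handles the typographic minus (U+2212), the multiplication sign
    (U+00D7) and ``x 10^k^`` superscript markup, e.g. ``"3.01 × 10^−2^"``
    becomes ``"3.01e-2"``.  Idempotent: already-normalised strings pass
    through unchanged.
    """
    s = text.strip().replace("−", "-")
    return _SCI_RE.sub(lambda m: "e" + m.group(1), s)


def _parse_probability(cell: str, where: str) -> float:
    norm = normalize_scientific(cell)
    try:
        p = float(norm)
    except ValueError:
        raise FormatError(f"unparseable p-value {cell!r} at {where}")
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p-value {p} outside (0, 1] at {where}")
    return p


# ---------------------------------------------------------------------------
# readers


def _read_raw(path, dialect: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep=_sep(dialect), dtype=str,
                            keep_default_na=False, header=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, missing header")
    return frame


def read_haplotype_table(path, dialect: str = "tsv") -> HaplotypeTable:
    """Read a gene x strain haplotype-call table.

    The first row must be a header naming strain columns; the first column
    holds gene symbols.  Unknown codes are rejected with the offending
    gene, strain and code named.
    """
    raw = _read_raw(path, dialect)
    strains = list(raw.columns[1:])
    # "B6" is both a strain name and a code, so a single code-like column
    # name is fine; a first row consisting entirely of codes is data.
    if len(strains) >= 2 and all(s in HAPLOTYPE_CODES for s in strains):
        raise FormatError(
            f"{path}: first row looks like data, not a header naming strains"
        )
    frame = raw.set_index(raw.columns[0])
    frame.index.name = "gene"
    frame = frame.apply(lambda col: col.str.strip())
    return HaplotypeTable(frame)


def read_proteome_table(path, dialect: str = "tsv") -> ProteomeTable:
    """Read a gene x strain protein-abundance table.

    Cells are period-decimal numbers or the missing token ``n/a``
    (case-insensitive; empty cells also count as missing).  Any other
    content is a :class:`FormatError` naming the row and column.
    """
    raw = _read_raw(path, dialect)
    strains = list(raw.columns[1:])
    frame = raw.set_index(raw.columns[0])
    frame.index.name = "gene"
    parsed = pd.DataFrame(index=frame.index, columns=strains, dtype=float)
    for gene, row in frame.iterrows():
        for strain in strains:
            cell = str(row[strain]).strip()
            if cell.casefold() in MISSING_TOKENS:
                parsed.at[gene, strain] = np.nan
                continue
            try:
                parsed.at[gene, strain] = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r},"
                    f" strain {strain!r}"
                )
    return ProteomeTable(parsed)


_CELLDEATH_COLUMNS = ("strain", "region", "treatment", "choline_dose",
                      "litter_id", "litter_mean")
_EXPECTED_DOSES = (0.0, 100.0, 250.0)


def read_celldeath_table(path, dialect: str = "tsv",
                         logger=None) -> list[CellDeathObservation]:
    """Read litter-level cell-death observations.

    Doses outside the study design {0, 100, 250} mg/kg are permitted but
    logged; negative litter means and duplicate
    (strain, region, treatment, dose, litter) keys are rejected.
    """
    import logging

    log = logger or logging.getLogger(__name__)
    raw = _read_raw(path, dialect)
    missing = [c for c in _CELLDEATH_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[CellDeathObservation] = []
    seen: set[tuple] = set()
    for i, row in raw.iterrows():
        where = f"{path}:{i + 2}"
        try:
            dose = float(row["choline_dose"])
            mean = float(row["litter_mean"])
        except ValueError as exc:
            raise FormatError(f"unparseable number at {where}: {exc}")
        if mean < 0:
            raise ValidationError(f"negative litter_mean {mean} at {where}")
        if dose not in _EXPECTED_DOSES:
            log.warning("unusual choline dose %s at %s", dose, where)
        obs = CellDeathObservation(
            strain=row["strain"].strip(),
            region=row["region"].strip(),
            treatment=row["treatment"].strip(),
            choline_dose=dose,
            litter_id=row["litter_id"].strip(),
            litter_mean=mean,
        )
        if obs.key() in seen:
            raise ValidationError(f"duplicate observation key {obs.key()} at {where}")
        seen.add(obs.key())
        records.append(obs)
    return records


def write_celldeath_table(obs: Iterable[CellDeathObservation], path,
                          dialect: str = "tsv") -> None:
    """Write observations in the format ``read_celldeath_table`` accepts."""
    frame = pd.DataFrame([o.__dict__ for o in obs], columns=_CELLDEATH_COLUMNS)
    frame.to_csv(path, sep=_sep(dialect), index=False)


def read_gwas_table(path, dialect: str = "tsv") -> list[SnpAssociationRecord]:
    """Read (variant, phenotype, p-value) association rows.

    P-values may use decimal, ASCII scientific or the published
    ``x 10^-k^`` notation; all are normalised by :func:`normalize_scientific`
    before parsing.  Records come back uncategorised.
    """
    raw = _read_raw(path, dialect)
    if raw.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (variant, phenotype, p)")
    records = []
    for i, row in raw.iterrows():
        where = f"{path}:{i + 2}"
        records.append(SnpAssociationRecord(
            variant_id=str(row.iloc[0]).strip(),
            phenotype_label=str(row.iloc[1]).strip(),
            p_value=_parse_probability(str(row.iloc[2]), where),
        ))
    return records


# ---------------------------------------------------------------------------
# bundled fixtures (transcriptions of the published strain-panel tables)


def _data_file(name: str):
    return resources.files("cholscreen").joinpath("data", name)


def load_haplotype_calls() -> HaplotypeTable:
    """The published 22-gene x 4-strain haplotype-call table."""
    with resources.as_file(_data_file("bxd_haplotypes.tsv")) as p:
        return read_haplotype_table(p)


def load_liver_proteome() -> ProteomeTable:
    """The published 5-gene x 4-strain liver proteome abundances."""
    with resources.as_file(_data_file("liver_proteome.tsv")) as p:
        return read_proteome_table(p)


def load_correlation_grid() -> pd.DataFrame:
    """The published Pearson-r grid: genes x (region, dose) conditions.

    Columns are a MultiIndex of (region, dose-in-mg/kg) pairs.
    """
    with resources.as_file(_data_file("reduction_correlations.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", index_col=0)
    cols = []
    for c in frame.columns:
        region, dose = c.rsplit("_", 1)
        cols.append((region, int(dose)))
    frame.columns = pd.MultiIndex.from_tuples(cols, names=["region", "dose"])
    return frame


def load_snp_associations(gene: str) -> list[SnpAssociationRecord]:
    """The published GWAS association rows for a final candidate gene."""
    name = f"{gene.casefold()}_snp_associations.tsv"
    try:
        with resources.as_file(_data_file(name)) as p:
            return read_gwas_table(p)
    except FileNotFoundError:
        raise KeyError(f"no bundled SNP associations for gene {gene!r}")


StudyTables = namedtuple(
    "StudyTables", ["haplotypes", "proteome", "correlations", "snp_tables"]
)


def load_study_tables() -> StudyTables:
    """All bundled study tables: haplotype calls, proteome, correlation
    grid and the per-gene SNP association tables."""
    return StudyTables(
        haplotypes=load_haplotype_calls(),
        proteome=load_liver_proteome(),
        correlations=load_correlation_grid(),
        snp_tables={
            "Cept1": load_snp_associations("Cept1"),
            "Slc44a1": load_snp_associations("Slc44a1"),
        },
    )
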