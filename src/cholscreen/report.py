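"""Funnel report container and renderers (TSV, JSON, Markdown).

The report records, per stage, the criterion applied, the retained gene
list and every removed gene with its reason, plus the final candidate
list and any per-gene annotations (e.g. SNP category counts).  Rendering
is deterministic: gene order follows the input order and a fixed report
always produces byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ValidationError

__all__ = ["StageResult", "FunnelReport", "render_report", "write_funnel_report"]

_FORMATS = ("tsv", "json", "markdown")
_EXT_TO_FORMAT = {".tsv": "tsv", ".json": "json", ".md": "markdown",
                  ".markdown": "markdown"}


@dataclass
class StageResult:
    name: str
    criterion: str
    retained: list[str]
    removed: dict[str, str]
    status: str = "COMPLETED"


@dataclass
class FunnelReport:
    stages: list[StageResult] = field(default_factory=list)
    final_candidates: list[str] = field(default_factory=list)
    config: dict | None = None
    annotations: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check the partition and nesting invariants.

        Every stage must partition its input gene set into retained and
        removed, and each stage's input must equal the previous stage's
        retained set.
        """
        prev: list[str] | None = None
        for stage in self.stages:
            if stage.status != "COMPLETED":
                continue
            overlap = set(stage.retained) & set(stage.removed)
            if overlap:
                raise ValidationError(
                    f"stage {stage.name!r}: genes both retained and removed:"
                    f" {sorted(overlap)}"
                )
            if prev is not None:
                inputs = set(stage.retained) | set(stage.removed)
                if inputs != set(prev):
                    raise ValidationError(
                        f"stage {stage.name!r}: input genes differ from the"
                        " previous stage's retained set"
                    )
            prev = stage.retained


def _render_tsv(report: FunnelReport) -> str:
    lines = ["stage\tcriterion\tstatus\tn_retained\tn_removed\tgene\tdisposition\treason"]
    for st in report.stages:
        base = f"{st.name}\t{st.criterion}\t{st.status}\t{len(st.retained)}\t{len(st.removed)}"
        if not st.retained and not st.removed:
            lines.append(base + "\t\t\t")
        for g in st.retained:
            lines.append(base + f"\t{g}\tretained\t")
        for g, reason in st.removed.items():
            lines.append(base + f"\t{g}\tremoved\t{reason}")
    lines.append("final_candidates\t\t\t\t\t" + ",".join(report.final_candidates) + "\t\t")
    return "\n".join(lines) + "\n"


def _render_json(report: FunnelReport) -> str:
    payload = {
        "config": report.config,
        "stages": [
            {
                "name": st.name,
                "criterion": st.criterion,
                "status": st.status,
                "retained": st.retained,
                "removed": st.removed,
            }
            for st in report.stages
        ],
        "final_candidates": report.final_candidates,
        "annotations": report.annotations,
    }
    return json.dumps(payload, indent=2) + "\n"


def _render_markdown(report: FunnelReport) -> str:
    out = ["# Screening funnel report", ""]
    if report.config:
        out += ["## Configuration", ""]
        for k in sorted(report.config):
            out.append(f"- `{k}`: {report.config[k]}")
        out.append("")
    for st in report.stages:
        out += [f"## Stage: {st.name} ({st.status})", "",
                f"Criterion: {st.criterion}", "",
                f"Retained {len(st.retained)}, removed {len(st.removed)}.", ""]
        if st.retained:
            out.append("Retained: " + ", ".join(st.retained))
            out.append("")
        if st.removed:
            out.append("| removed gene | reason |")
            out.append("| --- | --- |")
            for g, reason in st.removed.items():
                out.append(f"| {g} | {reason} |")
            out.append("")
    out += ["## Final candidates", "",
            ", ".join(report.final_candidates) if report.final_candidates
            else "(none)", ""]
    if report.annotations:
        out += ["## Annotations", ""]
        for gene in report.annotations:
            out.append(f"- {gene}: {json.dumps(report.annotations[gene])}")
        out.append("")
    return "\n".join(out)


_RENDERERS = {"tsv": _render_tsv, "json": _render_json,
              "markdown": _render_markdown}


def render_report(report: FunnelReport, fmt: str = "markdown") -> str:
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    return _RENDERERS[fmt](report)


def write_funnel_report(report: FunnelReport, path, fmt: str | None = None) -> None:
    """Write the report; the format defaults from the file extension."""
    path = Path(path)
    if fmt is None:
        fmt = _EXT_TO_FORMAT.get(path.suffix.lower(), "tsv")
    path.write_text(render_report(report, fmt), encoding="utf-8")
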