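"""Compliance-report assembly and rendering (text, TSV, JSON, HTML).

Rendering is deterministic: rows are ordered by (modality, stratum) and
the timestamp comes from an injectable clock, so identical audit results
produce byte-identical documents.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from string import Template
from typing import Callable, Optional, Sequence

from .compliance import (Deviation, ModalitySummary, ReferenceProtocol,
                         format_percent)

TSV_COLUMNS = ("modality", "stratum", "n_noncompliant", "pct_noncompliant",
               "n_total", "deviant_params", "n_compliant", "pct_compliant")


def repeat_offenders(summaries: Sequence[ModalitySummary]
                     ) -> dict[str, set[str]]:
    """Subjects deviant in two or more distinct parameters, with the
    parameter set — recurring per-subject patterns (e.g. TR together with
    flip angle) often point at deliberate SAR adjustments."""
    per_subject: dict[str, set[str]] = {}
    for summary in summaries:
        for dev in summary.deviations:
            per_subject.setdefault(dev.subject_id, set()).add(dev.parameter)
    return {s: params for s, params in per_subject.items()
            if len(params) >= 2}


def missing_parameter_roster(summaries: Sequence[ModalitySummary]
                             ) -> dict[str, int]:
    """Parameter -> number of missing-type deviations across all strata."""
    roster: dict[str, int] = {}
    for summary in summaries:
        for dev in summary.deviations:
            if dev.type == "missing":
                roster[dev.parameter] = roster.get(dev.parameter, 0) + 1
    return roster


@dataclass
class ComplianceReport:
    dataset_name: str
    timestamp: str
    tolerance: float
    summaries: list[ModalitySummary] = field(default_factory=list)
    vertical_deviations: list[Deviation] = field(default_factory=list)
    decimals: int = 2

    def __post_init__(self):
        self.summaries = sorted(
            self.summaries, key=lambda s: (s.modality_label, s.stratum))

    @property
    def repeat_offenders(self) -> dict[str, set[str]]:
        return repeat_offenders(self.summaries)

    @property
    def missing_roster(self) -> dict[str, int]:
        return missing_parameter_roster(self.summaries)

    def rows(self) -> list[dict]:
        out = []
        for s in self.summaries:
            out.append({
                "modality": s.modality_label,
                "stratum": s.stratum_label(),
                "n_noncompliant": s.n_noncompliant,
                "pct_noncompliant": format_percent(s.noncompliant_pct,
                                                   self.decimals),
                "n_total": s.n_total,
                "deviant_params": ";".join(sorted(s.deviant_parameters
                                                  | s.missing_parameters)),
                "n_compliant": s.n_compliant,
                "pct_compliant": format_percent(s.compliant_pct,
                                                self.decimals),
            })
        return out

    def to_json(self) -> dict:
        return {
            "dataset_name": self.dataset_name,
            "timestamp": self.timestamp,
            "tolerance": self.tolerance,
            "summaries": [s.to_json() for s in self.summaries],
            "vertical_deviations": [d.to_json()
                                    for d in self.vertical_deviations],
            "repeat_offenders": {s: sorted(p)
                                 for s, p in sorted(
                                     self.repeat_offenders.items())},
            "missing_parameter_roster": dict(
                sorted(self.missing_roster.items())),
        }


def build_report(dataset_name: str,
                 summaries: Sequence[ModalitySummary],
                 tolerance: float = 0.0,
                 vertical_deviations: Sequence[Deviation] = (),
                 clock: Optional[Callable[[], str]] = None,
                 decimals: int = 2) -> ComplianceReport:
    if clock is None:
        from datetime import datetime, timezone
        def clock():
            return datetime.now(timezone.utc).isoformat(timespec="seconds")
    return ComplianceReport(dataset_name=dataset_name,
                            timestamp=clock(),
                            tolerance=tolerance,
                            summaries=list(summaries),
                            vertical_deviations=list(vertical_deviations),
                            decimals=decimals)


def _deviation_from_json(raw: dict) -> Deviation:
    ref, obs = raw["reference_value"], raw["observed_value"]
    return Deviation(
        run_id=raw["run_id"], subject_id=raw["subject_id"],
        session_id=raw["session_id"], parameter=raw["parameter"],
        reference_value=tuple(ref) if isinstance(ref, list) else ref,
        observed_value=tuple(obs) if isinstance(obs, list) else obs,
        type=raw["type"], detail=raw.get("detail", ""))


def summary_from_json(raw: dict) -> ModalitySummary:
    return ModalitySummary(
        modality_label=raw["modality_label"],
        stratum=tuple(raw["stratum"].items()),
        n_noncompliant=raw["n_noncompliant"],
        n_total=raw["n_total"],
        noncompliant_pct=raw["noncompliant_pct"],
        compliant_pct=raw["compliant_pct"],
        deviant_parameters=set(raw["deviant_parameters"]),
        missing_parameters=set(raw["missing_parameters"]),
        subject_status=dict(raw["subject_status"]),
        deviations=[_deviation_from_json(d) for d in raw["deviations"]],
        reference=ReferenceProtocol(modality_label=raw["modality_label"],
                                    source=raw.get("reference_source",
                                                   "inferred")),
        tolerance=raw.get("tolerance", 0.0),
        low_support=raw.get("low_support", False))


def report_from_json(data: dict) -> ComplianceReport:
    """Rebuild a report from its JSON rendering (counts and percentages
    round-trip at full precision)."""
    return ComplianceReport(
        dataset_name=data["dataset_name"],
        timestamp=data["timestamp"],
        tolerance=data["tolerance"],
        summaries=[summary_from_json(s) for s in data["summaries"]],
        vertical_deviations=[_deviation_from_json(d)
                             for d in data.get("vertical_deviations", [])])


# ----------------------------------------------------------------------
# renderers

def render(report: ComplianceReport, format: str) -> str:
    if format == "json":
        return _render_json(report)
    if format == "tsv":
        return _render_tsv(report)
    if format == "text":
        return _render_text(report)
    if format == "html":
        return _render_html(report)
    raise ValueError(f"unknown report format: {format!r}")


def _render_json(report: ComplianceReport) -> str:
    return json.dumps(report.to_json(), indent=2, sort_keys=True) + "\n"


def _render_tsv(report: ComplianceReport) -> str:
    lines = ["\t".join(TSV_COLUMNS)]
    for row in report.rows():
        lines.append("\t".join(str(row[c]) for c in TSV_COLUMNS))
    return "\n".join(lines) + "\n"


def _render_text(report: ComplianceReport) -> str:
    head = [f"Compliance report: {report.dataset_name}",
            f"generated: {report.timestamp}   tolerance: {report.tolerance}",
            ""]
    if not report.summaries:
        return "\n".join(head + ["nothing audited", ""])
    rows = report.rows()
    widths = {c: max(len(c), *(len(str(r[c])) for r in rows))
              for c in TSV_COLUMNS}
    fmt = "  ".join(f"{{{c}:<{widths[c]}}}" for c in TSV_COLUMNS)
    body = [fmt.format(**{c: c for c in TSV_COLUMNS}),
            fmt.format(**{c: "-" * widths[c] for c in TSV_COLUMNS})]
    body += [fmt.format(**{c: str(r[c]) for c in TSV_COLUMNS}) for r in rows]
    tail = []
    roster = report.missing_roster
    if roster:
        tail.append("")
        tail.append("missing parameters (parameter: #runs affected):")
        tail += [f"  {name}: {count}" for name, count in sorted(roster.items())]
    offenders = report.repeat_offenders
    if offenders:
        tail.append("")
        tail.append("repeat offenders (deviant in >= 2 parameters):")
        tail += [f"  {subj}: {', '.join(sorted(params))}"
                 for subj, params in sorted(offenders.items())]
    if report.vertical_deviations:
        tail.append("")
        tail.append("vertical-audit deviations:")
        tail += [f"  {d.subject_id} {d.parameter} [{d.type}] "
                 f"ref={d.reference_value} obs={d.observed_value} {d.detail}"
                 for d in report.vertical_deviations]
    return "\n".join(head + body + tail) + "\n"


_HTML_TEMPLATE = Template("""\
<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Compliance report: $name</title>
<style>
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 4px 8px; text-align: left; }
th { background: #eee; }
.bad { color: #a00; font-weight: bold; }
</style></head>
<body>
<h1>Compliance report: $name</h1>
<p>generated: $timestamp &mdash; tolerance: $tolerance</p>
$body
</body></html>
""")


def _render_html(report: ComplianceReport) -> str:
    esc = html.escape
    if not report.summaries:
        body = "<p>nothing audited</p>"
    else:
        rows_html = []
        for row in report.rows():
            cells = "".join(f"<td>{esc(str(row[c]))}</td>"
                            for c in TSV_COLUMNS)
            rows_html.append(f"<tr>{cells}</tr>")
        header = "".join(f"<th>{esc(c)}</th>" for c in TSV_COLUMNS)
        body = (f"<table><thead><tr>{header}</tr></thead>"
                f"<tbody>{''.join(rows_html)}</tbody></table>")
        roster = report.missing_roster
        if roster:
            items = "".join(f"<li>{esc(n)}: {c}</li>"
                            for n, c in sorted(roster.items()))
            body += f"<h2>Missing parameters</h2><ul>{items}</ul>"
        offenders = report.repeat_offenders
        if offenders:
            items = "".join(
                f"<li class=\"bad\">{esc(s)}: "
                f"{esc(', '.join(sorted(p)))}</li>"
                for s, p in sorted(offenders.items()))
            body += f"<h2>Repeat offenders</h2><ul>{items}</ul>"
        if report.vertical_deviations:
            items = "".join(
                f"<li>{esc(d.subject_id)} {esc(d.parameter)} [{esc(d.type)}] "
                f"ref={esc(str(d.reference_value))} "
                f"obs={esc(str(d.observed_value))} {esc(d.detail)}</li>"
                for d in report.vertical_deviations)
            body += f"<h2>Vertical-audit deviations</h2><ul>{items}</ul>"
    return _HTML_TEMPLATE.substitute(name=esc(report.dataset_name),
                                     timestamp=esc(report.timestamp),
                                     tolerance=report.tolerance,
                                     body=body)


def write_reports(report: ComplianceReport, out_dir, formats=("html", "text",
                                                              "json", "tsv")):
    """Write report.<ext> files; returns the list of paths written."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"html": "html", "text": "txt", "json": "json", "tsv": "tsv"}
    paths = []
    for fmt in formats:
        path = out_dir / f"report.{ext[fmt]}"
        path.write_text(render(report, fmt))
        paths.append(path)
    return paths
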