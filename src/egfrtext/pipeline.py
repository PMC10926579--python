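"""End-to-end batch processing of laboratory export tables.

Reads a delimited export in one of the configured dataset dialects, filters
to biomarker-relevant rows by keyword, runs each report body through
RTF stripping → normalization → section splitting → grammar extraction,
and tallies an extraction summary (status counts, per-location counts,
multi-location distribution, location-pair combinations).

Dialects are data, not code: the packaged ``dialects.yaml`` describes the
two supported export layouts (a multi-column RTF dialect and a single
plain-text column dialect) and new sources are added as config blocks.
Row-level failures never abort a batch — they surface as unparseable
records routed to a reject list for manual review.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .extraction import EGFRResult, extract_result, result_to_records
from .grammar import Grammar
from .lexer import Lexicon, normalize, split_sections
from .rtf import RtfConfig, RtfPayload, rtf_to_text

__all__ = [
    "DatasetDialect",
    "ExtractionSummary",
    "ConfigError",
    "load_dialects",
    "filter_records",
    "run_extraction",
    "merge_duplicate_results",
    "summarize_records",
]

RECORD_COLUMNS = ["result_id", "patient_id", "status", "location", "specific", "source_section"]


class ConfigError(ValueError):
    """Raised for inconsistent dialect / pipeline configuration."""


@dataclass(frozen=True)
class DatasetDialect:
    """How one laboratory export stores its reports."""

    name: str
    filter_columns: tuple[str, ...]
    body_column: str
    body_is_rtf: bool
    headers: tuple[str, ...]
    result_section_priority: tuple[str, ...]
    result_id_column: str = "RESULT_ID"
    patient_id_column: str = "ULI"

    def __post_init__(self) -> None:
        known = set(self.headers)
        for label in self.result_section_priority:
            if label not in known:
                raise ConfigError(
                    f"dialect {self.name!r}: priority section {label!r} not in header list"
                )


def load_dialects(path: str | Path | None = None) -> dict[str, DatasetDialect]:
    """Load dialect presets from YAML (the packaged file by default)."""
    if path is None:
        text = resources.files("egfrtext.data").joinpath("dialects.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    dialects: dict[str, DatasetDialect] = {}
    for name, block in doc.get("dialects", {}).items():
        dialects[name] = DatasetDialect(
            name=name,
            filter_columns=tuple(block["filter_columns"]),
            body_column=block["body_column"],
            body_is_rtf=bool(block.get("body_is_rtf", False)),
            headers=tuple(block["headers"]),
            result_section_priority=tuple(block["result_section_priority"]),
            result_id_column=block.get("result_id_column", "RESULT_ID"),
            patient_id_column=block.get("patient_id_column", "ULI"),
        )
    return dialects


def filter_records(table: pd.DataFrame, dialect: DatasetDialect, keyword: str = "egfr") -> pd.DataFrame:
    """Keep rows mentioning *keyword* (case-insensitive substring) in any
    of the dialect's filter columns.  Row order is preserved; rows with a
    missing patient identifier are retained.
    """
    missing = [c for c in dialect.filter_columns if c not in table.columns]
    if missing:
        raise ConfigError(f"dialect {dialect.name!r}: missing filter column(s) {missing}")
    if table.empty:
        return table.copy()
    mask = pd.Series(False, index=table.index)
    for col in dialect.filter_columns:
        mask |= table[col].fillna("").astype(str).str.contains(keyword, case=False, regex=False)
    return table[mask].copy()


def restrict_to_patients(
    table: pd.DataFrame, dialect: DatasetDialect, allowlist: Iterable[str]
) -> pd.DataFrame:
    """Keep rows whose patient identifier is in *allowlist*.

    Stands in for registry-based cohort restriction when a vetted patient
    list is available; rows with an empty identifier are dropped (they
    cannot be confirmed against the list).
    """
    if dialect.patient_id_column not in table.columns:
        raise ConfigError(f"dialect {dialect.name!r}: missing patient column {dialect.patient_id_column!r}")
    allowed = {str(a) for a in allowlist}
    ids = table[dialect.patient_id_column].fillna("").astype(str)
    return table[(ids != "") & ids.isin(allowed)].copy()


@dataclass
class ExtractionSummary:
    """Aggregate counts over one extraction batch."""

    n_rows: int = 0
    n_unique_results: int = 0
    status_counts: dict[str, int] = field(default_factory=dict)
    location_counts: dict[str, int] = field(default_factory=dict)
    multi_location_counts: dict[str, int] = field(default_factory=dict)  # keys "2","3","4+"
    combination_counts: dict[str, int] = field(default_factory=dict)  # "exon19+T790M" → n

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_rows": self.n_rows,
            "n_unique_results": self.n_unique_results,
            "status_counts": dict(sorted(self.status_counts.items())),
            "location_counts": dict(sorted(self.location_counts.items())),
            "multi_location_counts": dict(sorted(self.multi_location_counts.items())),
            "combination_counts": dict(sorted(self.combination_counts.items())),
        }


def _summarize(results: Sequence[EGFRResult], result_ids: Sequence[str]) -> ExtractionSummary:
    summary = ExtractionSummary(n_rows=len(results))
    status_counter: Counter[str] = Counter()
    loc_counter: Counter[str] = Counter()
    multi_counter: Counter[str] = Counter()
    combo_counter: Counter[str] = Counter()
    for res in results:
        status_counter[res.status] += 1
        if res.status == "identified":
            locs = [m.location for m in res.mutations]
            for loc in locs:
                loc_counter[loc] += 1
            k = len(locs)
            if k >= 2:
                multi_counter["4+" if k >= 4 else str(k)] += 1
                combo_counter["+".join(sorted(locs))] += 1
    summary.status_counts = dict(status_counter)
    summary.location_counts = dict(loc_counter)
    summary.multi_location_counts = dict(multi_counter)
    summary.combination_counts = dict(combo_counter)
    nonempty_ids = {rid for rid in result_ids if rid}
    summary.n_unique_results = len(nonempty_ids) if nonempty_ids else len(results)
    return summary


def run_extraction(
    table: pd.DataFrame,
    dialect: DatasetDialect,
    lexicon: Lexicon,
    grammar: Grammar,
    rtf_config: RtfConfig | None = None,
) -> tuple[pd.DataFrame, ExtractionSummary, list[EGFRResult]]:
    """Run the full lexical + syntax pipeline over a (filtered) table.

    Returns the long-format record table (one row per mutation call, or one
    row per non-identified result), the batch summary, and the per-row
    :class:`EGFRResult` objects in input order.
    """
    if dialect.body_column not in table.columns and not table.empty:
        raise ConfigError(f"dialect {dialect.name!r}: missing body column {dialect.body_column!r}")

    records: list[dict[str, str]] = []
    results: list[EGFRResult] = []
    result_ids: list[str] = []
    for _, row in table.iterrows():
        rid = str(row.get(dialect.result_id_column, "") or "")
        pid = str(row.get(dialect.patient_id_column, "") or "")
        body = row.get(dialect.body_column, "")
        body = "" if pd.isna(body) else str(body)
        if not body.strip():
            result = EGFRResult(status="unparseable", reason="empty report body")
        else:
            if dialect.body_is_rtf:
                body = rtf_to_text(RtfPayload(raw=body, source_id=rid), rtf_config).text
            report = split_sections(normalize(body), dialect.headers)
            result = extract_result(report, lexicon, grammar, dialect.result_section_priority)
        results.append(result)
        result_ids.append(rid)
        records.extend(result_to_records(result, result_id=rid, patient_id=pid))

    records_df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    summary = _summarize(results, result_ids)
    return records_df, summary, results


def summarize_records(records: pd.DataFrame) -> ExtractionSummary:
    """Recompute an :class:`ExtractionSummary` from a long-format record table."""
    summary = ExtractionSummary()
    if records.empty:
        return summary
    per_result = records.groupby("result_id", sort=False)
    summary.n_rows = per_result.ngroups
    summary.n_unique_results = per_result.ngroups
    status_counter: Counter[str] = Counter()
    loc_counter: Counter[str] = Counter()
    multi_counter: Counter[str] = Counter()
    combo_counter: Counter[str] = Counter()
    for _, group in per_result:
        status = group["status"].iloc[0]
        status_counter[status] += 1
        if status == "identified":
            locs = [l for l in group["location"].tolist() if l]
            for loc in locs:
                loc_counter[loc] += 1
            if len(locs) >= 2:
                multi_counter["4+" if len(locs) >= 4 else str(len(locs))] += 1
                combo_counter["+".join(sorted(locs))] += 1
    summary.status_counts = dict(status_counter)
    summary.location_counts = dict(loc_counter)
    summary.multi_location_counts = dict(multi_counter)
    summary.combination_counts = dict(combo_counter)
    return summary


def merge_duplicate_results(records: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Collapse rows sharing a result identifier.

    A source table can carry one test result across several rows; grouping
    on the result id merges their location records and drops exact
    duplicates.  Results whose rows disagree on status keep the first
    status (row order) and are reported as data-quality warnings.
    """
    if records.empty:
        return records.copy(), []
    warnings: list[str] = []
    merged_parts: list[pd.DataFrame] = []
    for rid, group in records.groupby("result_id", sort=False):
        statuses = group["status"].unique()
        if len(statuses) > 1:
            warnings.append(f"result {rid!r}: conflicting statuses {sorted(statuses)}")
            group = group[group["status"] == group["status"].iloc[0]]
        merged_parts.append(group.drop_duplicates(subset=["result_id", "location", "specific"]))
    merged = pd.concat(merged_parts, ignore_index=True)
    return merged, warnings


def write_records(records: pd.DataFrame, path: str | Path, fmt: str = "csv") -> None:
    """Write the record table as RFC-4180-style CSV or JSON lines."""
    path = Path(path)
    if fmt == "csv":
        records.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for _, row in records.iterrows():
                fh.write(json.dumps(row.to_dict(), sort_keys=True) + "\n")
    else:
        raise ConfigError(f"unknown output format {fmt!r}")
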