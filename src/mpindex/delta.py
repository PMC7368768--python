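"""Delta-file ingestion and snapshot import/export.

The reference registry shares identity creations and modifications as a
daily "delta" CSV: semicolon-separated, ISO-LATIN-1 encoded, with a
mandatory header naming the national-chart columns (``ssn`` first, then
the traits in chart order; an optional trailing ``status`` column carries
the affiliation status and is filtered on when present). Dates are
``DD/MM/YYYY``. Diacritics are preserved byte-exactly.

Each well-formed row is validated (SSN mandatory in this workflow) and
routed through the deterministic matcher under the reference domain; the
row's operation is inferred, not declared: an SSN already reconciled in
the reference domain means UPDATE, anything else means CREATE. Rejected
rows are counted with their coded reasons, never silently dropped — the
ingest summary always satisfies read = created + updated + rejected.
"""

from __future__ import annotations

import copy
import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .matching import (DEFAULT_THRESHOLDS, DEFAULT_WEIGHTS, MatchWeights,
                       Thresholds, process_identity_event)
from .store import MPIStore, StoreError
from .traits import TRAIT_FIELDS

__all__ = [
    "DELTA_COLUMNS",
    "DeltaRecord",
    "IngestSummary",
    "read_delta_file",
    "write_delta_file",
    "apply_delta",
    "export_snapshot",
    "import_snapshot",
]

ENCODING = "iso-8859-1"
SEPARATOR = ";"

#: Mandatory delta columns, in national-chart order.
DELTA_COLUMNS = ("ssn",) + TRAIT_FIELDS

#: Snapshot CSV columns: both identifiers, then the chart traits.
SNAPSHOT_COLUMNS = ("fid", "ssn") + TRAIT_FIELDS


@dataclass
class DeltaRecord:
    """One parsed delta row; ``op`` is inferred at apply time."""

    line_no: int
    row: dict
    op: Optional[str] = None


@dataclass
class IngestSummary:
    read: int = 0
    created: int = 0
    updated: int = 0
    rejected: int = 0
    rejection_reasons: Counter = field(default_factory=Counter)
    branches: Counter = field(default_factory=Counter)

    @property
    def rejection_rate_pct(self) -> float:
        return 100.0 * self.rejected / self.read if self.read else 0.0


def read_delta_file(path) -> Tuple[List[DeltaRecord], List[str]]:
    """Parse a delta CSV into records plus a list of per-line format errors.

    Malformed rows (wrong column count) are reported with their line
    number and skipped; they never become records.
    """
    records: List[DeltaRecord] = []
    errors: List[str] = []
    with open(path, "r", encoding=ENCODING, newline="") as fh:
        reader = csv.reader(fh, delimiter=SEPARATOR)
        try:
            header = next(reader)
        except StopIteration:
            return records, ["line 1: empty file, header expected"]
        header = [h.strip() for h in header]
        missing = [c for c in DELTA_COLUMNS if c not in header]
        if missing:
            return records, [f"line 1: header lacks columns {missing}"]
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                errors.append(
                    f"line {line_no}: expected {len(header)} columns, got {len(row)}")
                continue
            records.append(DeltaRecord(line_no=line_no,
                                       row=dict(zip(header, row))))
    return records, errors


def write_delta_file(path, rows: Sequence[dict],
                     include_status: bool = False) -> None:
    """Write delta rows in the canonical dialect (used by the simulator)."""
    columns = DELTA_COLUMNS + (("status",) if include_status else ())
    with open(path, "w", encoding=ENCODING, newline="") as fh:
        writer = csv.writer(fh, delimiter=SEPARATOR)
        writer.writerow(columns)
        for row in rows:
            writer.writerow([row.get(c, "") for c in columns])


def apply_delta(store: MPIStore, records: Sequence[DeltaRecord],
                dry_run: bool = False,
                weights: MatchWeights = DEFAULT_WEIGHTS,
                thresholds: Thresholds = DEFAULT_THRESHOLDS) -> IngestSummary:
    """Route delta records through the reference workflow.

    ``dry_run=True`` runs the whole ingest against a disposable copy of
    the store (the test-environment pass): the summary is identical to
    what a real run would produce, and the store is left untouched.
    """
    ref = store.reference_domain()
    if ref is None:
        raise StoreError("no REFERENCE domain registered")
    if dry_run:
        store = copy.deepcopy(store)

    summary = IngestSummary()
    for record in records:
        summary.read += 1
        status = str(record.row.get("status", "") or "").strip().lower()
        if status and status != "valid":
            summary.rejected += 1
            summary.rejection_reasons["AFFILIATION_STATUS"] += 1
            continue
        ssn_raw = str(record.row.get("ssn", "") or "").strip()
        op = "UPDATE" if (ssn_raw and store.active_reconciliation(
            ref.domain_id, ssn_raw) is not None) else "CREATE"
        record.op = op
        try:
            outcome = process_identity_event(store, ref.domain_id, ssn_raw,
                                             record.row, event=op,
                                             weights=weights,
                                             thresholds=thresholds)
        except Exception as exc:  # validation failures become rejections
            summary.rejected += 1
            reasons = getattr(getattr(exc, "report", None), "reasons", None)
            for reason in (reasons or [type(exc).__name__]):
                summary.rejection_reasons[reason] += 1
            continue
        summary.branches[outcome.branch] += 1
        if op == "CREATE":
            summary.created += 1
        else:
            summary.updated += 1
    return summary


def export_snapshot(store: MPIStore, path, format: str = "jsonl") -> None:
    """Export the store; ``jsonl`` is the full round-trippable snapshot,
    ``csv`` a flat view of the central identities in chart column order.
    """
    if format == "jsonl":
        store.save(path)
    elif format == "csv":
        with open(path, "w", encoding=ENCODING, newline="") as fh:
            writer = csv.writer(fh, delimiter=SEPARATOR)
            writer.writerow(SNAPSHOT_COLUMNS)
            for fid in sorted(store.centrals):
                central = store.centrals[fid]
                row = central.traits.to_row()
                row["fid"] = central.fid
                row["ssn"] = central.ssn.raw if central.ssn else ""
                writer.writerow([row.get(c, "") for c in SNAPSHOT_COLUMNS])
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_snapshot(path, seed: Optional[int] = None, clock=None) -> MPIStore:
    """Rebuild a store (indexes included) from a JSON-lines snapshot."""
    return MPIStore.load(path, seed=seed, clock=clock)
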