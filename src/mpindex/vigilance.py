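"""Identity vigilance: duplicate lifecycle, merging, and anomaly statistics.

Duplicates — two central profiles referring to the same person — enter the
vigilance queue as *potential* cases, either flagged by the matching
algorithm at admission time (ambiguous exact matches) or spotted by the
surveillance scan over the store (profiles sharing a national identifier,
or carrying identical strict traits). A human vigilance cell then closes
each case: *merged*, with one profile becoming the master and the other a
deactivated slave whose reconciliations are re-pointed to the master, or
*dismissed*. Merged cases carry a cause label from the operational error
taxonomy: alternative use of marital and family name, spelling mistakes,
divergent local identifiers, or other.

Collisions — one profile shared by two different people — are the converse
failure; they are only ever reported by care structures and logged here
for manual treatment, never resolved automatically.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .store import (CollisionRecord, DuplicateCase, MPIError, MPIStore,
                    Reconciliation)
from .traits import normalize_name

__all__ = [
    "CAUSES",
    "VigilanceStats",
    "VigilanceError",
    "flag_duplicate",
    "dismiss_case",
    "merge_duplicates",
    "scan_potential_duplicates",
    "resolve_transitory",
    "report_collision",
    "vigilance_report",
    "throughput_summary",
]

CAUSES = ("MARITAL_NAME", "SPELLING", "LOCAL_ID", "OTHER")


class VigilanceError(MPIError):
    pass


@dataclass
class VigilanceStats:
    """Vigilance activity over a period, with the anomaly-cause breakdown."""

    period: Optional[Tuple[_dt.date, _dt.date]]
    days: int
    potential_count: int
    merged_count: int
    dismissed_count: int
    anomalies_total: int
    anomalies_per_day: float
    cause_distribution: Dict[str, float] = field(default_factory=dict)
    cause_counts: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "period_start": self.period[0].isoformat() if self.period else None,
            "period_end": self.period[1].isoformat() if self.period else None,
            "days": self.days,
            "potential_count": self.potential_count,
            "merged_count": self.merged_count,
            "dismissed_count": self.dismissed_count,
            "anomalies_total": self.anomalies_total,
            "anomalies_per_day": self.anomalies_per_day,
            "cause_distribution": dict(self.cause_distribution),
            "cause_counts": dict(self.cause_counts),
        }
        return out


def flag_duplicate(store: MPIStore, fid_a: str, fid_b: str,
                   origin: str = "operator") -> DuplicateCase:
    """Open a potential-duplicate case for two distinct active profiles."""
    if fid_a == fid_b:
        raise VigilanceError("a duplicate case needs two distinct FIDs")
    for fid in (fid_a, fid_b):
        central = store.get_central(fid)
        if central.status != "ACTIVE":
            raise VigilanceError(f"FID {fid} is not active")
    existing = store.open_case_for_pair(frozenset((fid_a, fid_b)))
    if existing is not None:
        raise VigilanceError(
            f"open case {existing.case_id} already covers this pair")
    case = DuplicateCase(case_id=len(store.duplicate_cases) + 1,
                         fid_a=fid_a, fid_b=fid_b, origin=origin,
                         opened_at=store.clock())
    store.record_case(case)
    return case


def dismiss_case(store: MPIStore, case_id: int) -> DuplicateCase:
    """Close a potential case as not-a-duplicate; cases never reopen."""
    case = _get_case(store, case_id)
    if case.status != "POTENTIAL":
        raise VigilanceError(f"case {case_id} is already closed")
    case.status = "DISMISSED"
    case.closed_at = store.clock()
    store.close_case_pair(case)
    return case


def _get_case(store: MPIStore, case_id: int) -> DuplicateCase:
    case = store.case_by_id(case_id)
    if case is None:
        raise VigilanceError(f"unknown duplicate case {case_id}")
    return case


def merge_duplicates(store: MPIStore, case_id: int, master: str, slave: str,
                     cause: str = "OTHER") -> DuplicateCase:
    """Merge a potential-duplicate pair: the slave profile is deactivated,
    points to the master, and its reconciliations are re-pointed so that
    any further research on the slave resolves to the master.
    """
    case = _get_case(store, case_id)
    if case.status != "POTENTIAL":
        raise VigilanceError(f"case {case_id} is already closed")
    if {master, slave} != {case.fid_a, case.fid_b}:
        raise VigilanceError("master/slave must be the case's FID pair")
    if cause not in CAUSES:
        raise VigilanceError(f"unknown cause label {cause!r}")
    master_central = store.get_central(master)
    slave_central = store.get_central(slave)
    if master_central.status != "ACTIVE":
        raise VigilanceError(f"master {master} is itself a merged slave")
    if slave_central.status != "ACTIVE":
        raise VigilanceError(f"slave {slave} is already merged")

    now = store.clock()
    store._index_remove(slave_central)
    slave_central.status = "MERGED_SLAVE"
    slave_central.merged_into = master
    slave_central.updated_at = now
    slave_central.audit_log.append((now.isoformat(), "MERGED_INTO", master))
    master_central.audit_log.append((now.isoformat(), "ABSORBED_SLAVE", slave))
    for rec in store.reconciliations_for_fid(slave):
        if rec.status != "DEACTIVATED":
            store.repoint_reconciliation(rec, master)
            rec.updated_at = now
    case.status = "MERGED"
    case.master = master
    case.slave = slave
    case.cause = cause
    case.closed_at = now
    store.close_case_pair(case)
    return case


def scan_potential_duplicates(store: MPIStore) -> List[DuplicateCase]:
    """Surveillance pass: flag active profile pairs that look like one person.

    Two active central identities are flagged when they share a national
    identifier, or when their strict traits (normalized names, birth
    date, sex) are identical. Pairs already covered by a case — open or
    closed — are skipped, so repeated scans are idempotent.
    """
    groups: Dict[tuple, List[str]] = {}
    for central in store.centrals.values():
        if central.status != "ACTIVE":
            continue
        if central.ssn is not None:
            groups.setdefault(("ssn", central.ssn.raw), []).append(central.fid)
        strict = ("strict",
                  normalize_name(central.traits.last_name),
                  normalize_name(central.traits.first_name),
                  central.traits.birth_date.isoformat(),
                  central.traits.sex)
        groups.setdefault(strict, []).append(central.fid)

    seen_pairs = {case.pair for case in store.duplicate_cases}
    opened: List[DuplicateCase] = []
    for fids in groups.values():
        if len(fids) < 2:
            continue
        fids = sorted(fids)
        for i in range(len(fids)):
            for j in range(i + 1, len(fids)):
                pair = frozenset((fids[i], fids[j]))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                opened.append(flag_duplicate(store, fids[i], fids[j],
                                             origin="algorithm"))
    return opened


def resolve_transitory(store: MPIStore, domain_id: str, local_id: str,
                       decision: str) -> Reconciliation:
    """Close a transitorily-modified reconciliation after vigilance review.

    ``ACCEPT`` restores VALID status and, in the reference workflow only,
    applies the pending modification to the central identity. ``REVERT``
    restores VALID status and discards the pending modification.
    """
    if decision not in ("ACCEPT", "REVERT"):
        raise VigilanceError("decision must be ACCEPT or REVERT")
    rec = store.active_reconciliation(domain_id, local_id)
    if rec is None or rec.status != "TRANSITORILY_MODIFIED":
        raise VigilanceError(
            f"({domain_id}, {local_id}) has no transitorily modified reconciliation")
    domain = store.get_domain(domain_id)
    master, _ = store.lookup(rec.fid)
    if decision == "ACCEPT" and domain.kind == "REFERENCE" and rec.pending_traits is not None:
        store.set_central_traits(master.fid, rec.pending_traits,
                                 ssn=rec.pending_ssn,
                                 note=f"transitory accepted via {local_id}")
    if master.temporarily_modified:
        master.temporarily_modified = False
    rec.status = "VALID"
    rec.pending_traits = None
    rec.pending_ssn = None
    rec.updated_at = store.clock()
    return rec


def report_collision(store: MPIStore, fid: str, reporter: str,
                     note: str = "") -> CollisionRecord:
    """Log a collision report (two people on one profile) for manual review."""
    store.get_central(fid)
    record = CollisionRecord(fid=fid, reporter=reporter, note=note,
                             reported_at=store.clock())
    store.collisions.append(record)
    return record


def _in_period(when: Optional[_dt.datetime],
               period: Optional[Tuple[_dt.date, _dt.date]]) -> bool:
    if when is None:
        return False
    if period is None:
        return True
    return period[0] <= when.date() <= period[1]


def vigilance_report(store: MPIStore,
                     period: Optional[Tuple[_dt.date, _dt.date]] = None) -> VigilanceStats:
    """Summarize vigilance activity: case counts, per-day anomaly rate, and
    the cause breakdown (percentages over cases closed with a cause).
    """
    opened = [c for c in store.duplicate_cases if _in_period(c.opened_at, period)]
    closed = [c for c in store.duplicate_cases if _in_period(c.closed_at, period)]
    collisions = [c for c in store.collisions if _in_period(c.reported_at, period)]

    if period is not None:
        days = (period[1] - period[0]).days + 1
    else:
        stamps = [c.opened_at.date() for c in opened if c.opened_at is not None]
        stamps += [c.reported_at.date() for c in collisions if c.reported_at is not None]
        days = (max(stamps) - min(stamps)).days + 1 if stamps else 1

    merged = [c for c in closed if c.status == "MERGED"]
    dismissed = [c for c in closed if c.status == "DISMISSED"]
    with_cause = [c for c in merged if c.cause is not None]
    cause_counts = {label: 0 for label in CAUSES}
    for case in with_cause:
        cause_counts[case.cause] += 1
    total_with_cause = sum(cause_counts.values())
    distribution = {}
    if total_with_cause:
        distribution = {label: 100.0 * n / total_with_cause
                        for label, n in cause_counts.items()}

    anomalies_total = len(opened) + len(collisions)
    return VigilanceStats(
        period=period,
        days=days,
        potential_count=sum(1 for c in opened if c.status == "POTENTIAL"),
        merged_count=len(merged),
        dismissed_count=len(dismissed),
        anomalies_total=anomalies_total,
        anomalies_per_day=anomalies_total / days,
        cause_distribution=distribution,
        cause_counts=cause_counts,
    )


def throughput_summary(profiles_retrieved: int, profiles_total: int,
                       anomalies: int, days: int,
                       daily_treated: int) -> Dict[str, float]:
    """Operational headline figures for one connected structure.

    Returns the retrieved share of the directory in percent, the mean
    anomalies per day, and the anomaly-to-daily-throughput ratio in
    percent.
    """
    per_day = anomalies / days
    return {
        "retrieved_share_pct": 100.0 * profiles_retrieved / profiles_total,
        "anomalies_per_day": per_day,
        "anomaly_ratio_pct": 100.0 * per_day / daily_treated,
    }
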