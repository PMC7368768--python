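"""The hierarchical federated identity store.

The store holds the three record kinds of the federation model:

* **Central identities** — the federal reference profiles, each keyed by a
  10-digit federated identifier (FID) allocated at random on creation.
* **Identification domains** — perimeters in which a patient carries a
  single local identifier. Exactly one domain is the REFERENCE domain (the
  national registry analogue); SECONDARY domains produce identities
  (longitudinal reconciliations) and CONSUMER domains only consume them
  (transversal reconciliations).
* **Reconciliations** — links ``(domain, local identifier) -> FID`` with a
  lifecycle status.

The reference domain holds the modification lock: as soon as a profile has
a valid reconciliation in the reference domain, only that domain may
modify the central traits.

Merged duplicates keep their slave profile with a ``merged_into`` pointer;
:meth:`MPIStore.lookup` follows those chains so any query against a slave
FID resolves to the active master.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from .ssn import SSN, validate_ssn
from .traits import IdentityTraits, normalize_name, parse_date

__all__ = [
    "MPIStore",
    "IdentificationDomain",
    "CentralIdentity",
    "Reconciliation",
    "DuplicateCase",
    "CollisionRecord",
    "ReconciliationReport",
    "MPIError",
    "DomainError",
    "UnknownFID",
    "StoreError",
]

FID_LENGTH = 10
_FID_SPACE = 10 ** FID_LENGTH

DOMAIN_KINDS = ("REFERENCE", "SECONDARY", "CONSUMER")
LONGITUDINAL = "LONGITUDINAL"
TRANSVERSAL = "TRANSVERSAL"


class MPIError(Exception):
    """Base class for store and workflow errors."""


class DomainError(MPIError):
    pass


class UnknownFID(MPIError):
    pass


class StoreError(MPIError):
    pass


@dataclass
class IdentificationDomain:
    domain_id: str
    kind: str
    description: str = ""

    @property
    def mode(self) -> str:
        return LONGITUDINAL if self.kind in ("REFERENCE", "SECONDARY") else TRANSVERSAL


@dataclass
class CentralIdentity:
    """A federal identity profile; the reference record of the MPI."""

    fid: str
    traits: IdentityTraits
    ssn: Optional[SSN] = None
    status: str = "ACTIVE"  # ACTIVE | MERGED_SLAVE
    merged_into: Optional[str] = None
    temporarily_modified: bool = False
    created_at: Optional[_dt.datetime] = None
    updated_at: Optional[_dt.datetime] = None
    audit_log: List[tuple] = field(default_factory=list)


@dataclass
class Reconciliation:
    """The link between one (domain, local identifier) pair and a FID."""

    domain_id: str
    local_id: str
    fid: str
    status: str = "VALID"  # VALID | TRANSITORILY_MODIFIED | DEACTIVATED
    mode: str = LONGITUDINAL
    pending_traits: Optional[IdentityTraits] = None
    pending_ssn: Optional[SSN] = None
    created_at: Optional[_dt.datetime] = None
    updated_at: Optional[_dt.datetime] = None

    @property
    def key(self) -> Tuple[str, str]:
        return (self.domain_id, self.local_id)


@dataclass
class DuplicateCase:
    """A vigilance item tracking two FIDs from potential to merged/dismissed."""

    case_id: int
    fid_a: str
    fid_b: str
    status: str = "POTENTIAL"  # POTENTIAL | MERGED | DISMISSED
    origin: str = "algorithm"
    master: Optional[str] = None
    slave: Optional[str] = None
    cause: Optional[str] = None
    opened_at: Optional[_dt.datetime] = None
    closed_at: Optional[_dt.datetime] = None

    @property
    def pair(self) -> frozenset:
        return frozenset((self.fid_a, self.fid_b))


@dataclass
class CollisionRecord:
    fid: str
    reporter: str
    note: str
    reported_at: Optional[_dt.datetime] = None


@dataclass
class ReconciliationReport:
    total: int
    longitudinal: int
    transversal: int
    longitudinal_share_pct: float
    by_status: Dict[str, int]


class MPIStore:
    """In-memory federated store with seedable FID allocation.

    ``clock`` is injectable for deterministic timestamps in tests; it must
    be a zero-argument callable returning a :class:`datetime.datetime`.
    """

    def __init__(self, seed: Optional[int] = None,
                 clock: Optional[Callable[[], _dt.datetime]] = None):
        self.rng = random.Random(seed)
        self.clock = clock or _dt.datetime.now
        self.domains: Dict[str, IdentificationDomain] = {}
        self.centrals: Dict[str, CentralIdentity] = {}
        #: all reconciliation records, including deactivated history
        self.reconciliations: List[Reconciliation] = []
        self._recs_by_key: Dict[Tuple[str, str], List[Reconciliation]] = {}
        self._recs_by_fid: Dict[str, List[Reconciliation]] = {}
        self._cases_by_id: Dict[int, DuplicateCase] = {}
        self._open_cases_by_pair: Dict[frozenset, DuplicateCase] = {}
        self.duplicate_cases: List[DuplicateCase] = []
        self.collisions: List[CollisionRecord] = []
        # blocking indexes over ACTIVE central identities
        self._by_ssn: Dict[str, set] = {}
        self._by_last_birth: Dict[tuple, set] = {}
        self._by_first_birth: Dict[tuple, set] = {}
        self._by_last_first: Dict[tuple, set] = {}

    # -- domains -----------------------------------------------------------

    def register_domain(self, domain_id: str, kind: str,
                        description: str = "") -> IdentificationDomain:
        if kind not in DOMAIN_KINDS:
            raise DomainError(f"unknown domain kind {kind!r}")
        if domain_id in self.domains:
            raise DomainError(f"domain {domain_id!r} already registered")
        if kind == "REFERENCE" and self.reference_domain() is not None:
            raise DomainError("a REFERENCE domain already exists")
        domain = IdentificationDomain(domain_id=domain_id, kind=kind,
                                      description=description)
        self.domains[domain_id] = domain
        return domain

    def reference_domain(self) -> Optional[IdentificationDomain]:
        for domain in self.domains.values():
            if domain.kind == "REFERENCE":
                return domain
        return None

    def get_domain(self, domain_id: str) -> IdentificationDomain:
        try:
            return self.domains[domain_id]
        except KeyError:
            raise DomainError(f"domain {domain_id!r} is not registered") from None

    # -- FID allocation ----------------------------------------------------

    def allocate_fid(self) -> str:
        """Draw an unused zero-padded 10-digit FID by rejection sampling."""
        if len(self.centrals) >= _FID_SPACE:
            raise StoreError("FID space exhausted")
        while True:
            fid = f"{self.rng.randrange(_FID_SPACE):0{FID_LENGTH}d}"
            if fid not in self.centrals:
                return fid

    # -- blocking indexes --------------------------------------------------

    @staticmethod
    def _block_keys(traits: IdentityTraits, ssn: Optional[SSN]):
        last = normalize_name(traits.last_name, fold_diacritics=True)
        first = normalize_name(traits.first_name, fold_diacritics=True)
        birth = traits.birth_date
        return (ssn.raw if ssn else None,
                (last, birth), (first, birth), (last, first))

    def _index_add(self, central: CentralIdentity) -> None:
        ssn_key, lb, fb, lf = self._block_keys(central.traits, central.ssn)
        if ssn_key:
            self._by_ssn.setdefault(ssn_key, set()).add(central.fid)
        self._by_last_birth.setdefault(lb, set()).add(central.fid)
        self._by_first_birth.setdefault(fb, set()).add(central.fid)
        self._by_last_first.setdefault(lf, set()).add(central.fid)

    def _index_remove(self, central: CentralIdentity) -> None:
        ssn_key, lb, fb, lf = self._block_keys(central.traits, central.ssn)
        if ssn_key:
            self._by_ssn.get(ssn_key, set()).discard(central.fid)
        self._by_last_birth.get(lb, set()).discard(central.fid)
        self._by_first_birth.get(fb, set()).discard(central.fid)
        self._by_last_first.get(lf, set()).discard(central.fid)

    def candidate_fids(self, traits: IdentityTraits, ssn: Optional[SSN]) -> set:
        """Union of the blocking buckets for an incoming record."""
        ssn_key, lb, fb, lf = self._block_keys(traits, ssn)
        out: set = set()
        if ssn_key:
            out |= self._by_ssn.get(ssn_key, set())
        out |= self._by_last_birth.get(lb, set())
        out |= self._by_first_birth.get(fb, set())
        out |= self._by_last_first.get(lf, set())
        return out

    # -- central identities ------------------------------------------------

    def create_central_identity(self, traits: IdentityTraits,
                                ssn: Optional[SSN] = None) -> CentralIdentity:
        now = self.clock()
        central = CentralIdentity(fid=self.allocate_fid(), traits=traits, ssn=ssn,
                                  created_at=now, updated_at=now)
        central.audit_log.append((now.isoformat(), "CREATED", ""))
        self.centrals[central.fid] = central
        self._index_add(central)
        return central

    def get_central(self, fid: str) -> CentralIdentity:
        try:
            return self.centrals[fid]
        except KeyError:
            raise UnknownFID(f"unknown FID {fid!r}") from None

    def lookup(self, fid: str) -> Tuple[CentralIdentity, List[str]]:
        """Resolve a FID to its active master, following merge pointers.

        Returns the master profile and the resolution path (entry FID
        first, master last).
        """
        central = self.get_central(fid)
        path = [fid]
        while central.status == "MERGED_SLAVE":
            central = self.get_central(central.merged_into)
            path.append(central.fid)
        return central, path

    def set_central_traits(self, fid: str, traits: IdentityTraits,
                           ssn: Optional[SSN] = None, note: str = "") -> None:
        """Replace a profile's traits, keeping the blocking indexes current."""
        central = self.get_central(fid)
        if central.status != "ACTIVE":
            raise StoreError(f"FID {fid} is a merged slave; modify its master")
        self._index_remove(central)
        central.traits = traits
        if ssn is not None:
            central.ssn = ssn
        central.updated_at = self.clock()
        central.audit_log.append((central.updated_at.isoformat(), "MODIFIED", note))
        self._index_add(central)

    def has_reference_reconciliation(self, fid: str) -> bool:
        ref = self.reference_domain()
        if ref is None:
            return False
        return any(rec.fid == fid and rec.status != "DEACTIVATED"
                   for rec in self.reconciliations
                   if rec.domain_id == ref.domain_id)

    def apply_central_modification(self, fid: str, new_traits: IdentityTraits,
                                   domain_id: str,
                                   ssn: Optional[SSN] = None) -> str:
        """Apply or block a central-trait modification under the reference lock.

        Once a profile is reconciled in the reference domain, only that
        domain may modify the central identity; any other caller gets
        ``"BLOCKED"`` and the traits stay untouched.
        """
        domain = self.get_domain(domain_id)
        central = self.get_central(fid)
        if central.status != "ACTIVE":
            raise StoreError(f"FID {fid} is a merged slave; modify its master")
        if domain.kind != "REFERENCE" and self.has_reference_reconciliation(fid):
            central.audit_log.append(
                (self.clock().isoformat(), "MODIFICATION_BLOCKED", domain_id))
            return "BLOCKED"
        self.set_central_traits(fid, new_traits, ssn=ssn, note=f"by {domain_id}")
        return "APPLIED"

    # -- reconciliations ---------------------------------------------------

    def active_reconciliation(self, domain_id: str, local_id: str) -> Optional[Reconciliation]:
        for rec in self._recs_by_key.get((domain_id, local_id), ()):
            if rec.status != "DEACTIVATED":
                return rec
        return None

    def add_reconciliation(self, domain_id: str, local_id: str, fid: str,
                           status: str = "VALID") -> Reconciliation:
        domain = self.get_domain(domain_id)
        self.get_central(fid)
        if self.active_reconciliation(domain_id, local_id) is not None:
            raise StoreError(
                f"active reconciliation already exists for ({domain_id}, {local_id})")
        now = self.clock()
        rec = Reconciliation(domain_id=domain_id, local_id=local_id, fid=fid,
                             status=status, mode=domain.mode,
                             created_at=now, updated_at=now)
        self.reconciliations.append(rec)
        self._recs_by_key.setdefault(rec.key, []).append(rec)
        self._recs_by_fid.setdefault(rec.fid, []).append(rec)
        return rec

    def reconciliations_for_fid(self, fid: str) -> List[Reconciliation]:
        return list(self._recs_by_fid.get(fid, ()))

    def repoint_reconciliation(self, rec: Reconciliation, new_fid: str) -> None:
        """Move a reconciliation to another FID (used by duplicate merging)."""
        self.get_central(new_fid)
        self._recs_by_fid.get(rec.fid, []).remove(rec)
        rec.fid = new_fid
        self._recs_by_fid.setdefault(new_fid, []).append(rec)

    # -- vigilance case registry ------------------------------------------

    def record_case(self, case: DuplicateCase) -> None:
        self.duplicate_cases.append(case)
        self._cases_by_id[case.case_id] = case
        if case.status == "POTENTIAL":
            self._open_cases_by_pair[case.pair] = case

    def case_by_id(self, case_id: int) -> Optional[DuplicateCase]:
        return self._cases_by_id.get(case_id)

    def open_case_for_pair(self, pair: frozenset) -> Optional[DuplicateCase]:
        return self._open_cases_by_pair.get(pair)

    def close_case_pair(self, case: DuplicateCase) -> None:
        self._open_cases_by_pair.pop(case.pair, None)

    def reconciliations_report(self, domain_id: Optional[str] = None,
                               mode: Optional[str] = None,
                               period: Optional[tuple] = None) -> ReconciliationReport:
        """Counts by mode and status, with the longitudinal share in percent."""
        records = [rec for rec in self.reconciliations
                   if rec.status != "DEACTIVATED"]
        if domain_id is not None:
            records = [rec for rec in records if rec.domain_id == domain_id]
        if mode is not None:
            records = [rec for rec in records if rec.mode == mode]
        if period is not None:
            start, end = period
            records = [rec for rec in records
                       if rec.created_at is not None
                       and start <= rec.created_at.date() <= end]
        total = len(records)
        longitudinal = sum(1 for rec in records if rec.mode == LONGITUDINAL)
        transversal = total - longitudinal
        share = 100.0 * longitudinal / total if total else 0.0
        by_status: Dict[str, int] = {}
        for rec in records:
            by_status[rec.status] = by_status.get(rec.status, 0) + 1
        return ReconciliationReport(total=total, longitudinal=longitudinal,
                                    transversal=transversal,
                                    longitudinal_share_pct=share,
                                    by_status=by_status)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write a deterministic JSON-lines snapshot of the whole store."""
        with open(path, "w", encoding="utf-8") as fh:
            for domain_id in sorted(self.domains):
                d = self.domains[domain_id]
                fh.write(_line("domain", {"domain_id": d.domain_id, "kind": d.kind,
                                          "description": d.description}))
            for fid in sorted(self.centrals):
                c = self.centrals[fid]
                fh.write(_line("central", {
                    "fid": c.fid,
                    "ssn": c.ssn.raw if c.ssn else None,
                    "traits": c.traits.to_row(),
                    "status": c.status,
                    "merged_into": c.merged_into,
                    "temporarily_modified": c.temporarily_modified,
                    "created_at": _ts(c.created_at),
                    "updated_at": _ts(c.updated_at),
                    "audit_log": [list(entry) for entry in c.audit_log],
                }))
            for r in sorted(self.reconciliations,
                            key=lambda r: (r.domain_id, r.local_id,
                                           _ts(r.created_at) or "", r.fid)):
                fh.write(_line("reconciliation", {
                    "domain_id": r.domain_id, "local_id": r.local_id,
                    "fid": r.fid, "status": r.status, "mode": r.mode,
                    "pending_traits": r.pending_traits.to_row() if r.pending_traits else None,
                    "pending_ssn": r.pending_ssn.raw if r.pending_ssn else None,
                    "created_at": _ts(r.created_at), "updated_at": _ts(r.updated_at),
                }))
            for case in self.duplicate_cases:
                fh.write(_line("duplicate_case", {
                    "case_id": case.case_id, "fid_a": case.fid_a, "fid_b": case.fid_b,
                    "status": case.status, "origin": case.origin,
                    "master": case.master, "slave": case.slave, "cause": case.cause,
                    "opened_at": _ts(case.opened_at), "closed_at": _ts(case.closed_at),
                }))
            for col in self.collisions:
                fh.write(_line("collision", {
                    "fid": col.fid, "reporter": col.reporter, "note": col.note,
                    "reported_at": _ts(col.reported_at),
                }))

    @classmethod
    def load(cls, path, seed: Optional[int] = None,
             clock: Optional[Callable[[], _dt.datetime]] = None) -> "MPIStore":
        store = cls(seed=seed, clock=clock)
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                kind, payload = obj["kind"], obj["data"]
                if kind == "domain":
                    store.domains[payload["domain_id"]] = IdentificationDomain(**payload)
                elif kind == "central":
                    central = CentralIdentity(
                        fid=payload["fid"],
                        traits=_traits_from_row(payload["traits"]),
                        ssn=_ssn_or_none(payload["ssn"]),
                        status=payload["status"],
                        merged_into=payload["merged_into"],
                        temporarily_modified=payload["temporarily_modified"],
                        created_at=_dts(payload["created_at"]),
                        updated_at=_dts(payload["updated_at"]),
                        audit_log=[tuple(entry) for entry in payload["audit_log"]],
                    )
                    store.centrals[central.fid] = central
                    if central.status == "ACTIVE":
                        store._index_add(central)
                elif kind == "reconciliation":
                    rec = Reconciliation(
                        domain_id=payload["domain_id"], local_id=payload["local_id"],
                        fid=payload["fid"], status=payload["status"],
                        mode=payload["mode"],
                        pending_traits=(_traits_from_row(payload["pending_traits"])
                                        if payload["pending_traits"] else None),
                        pending_ssn=_ssn_or_none(payload["pending_ssn"]),
                        created_at=_dts(payload["created_at"]),
                        updated_at=_dts(payload["updated_at"]),
                    )
                    store.reconciliations.append(rec)
                    store._recs_by_key.setdefault(rec.key, []).append(rec)
                elif kind == "duplicate_case":
                    payload["opened_at"] = _dts(payload["opened_at"])
                    payload["closed_at"] = _dts(payload["closed_at"])
                    store.record_case(DuplicateCase(**payload))
                elif kind == "collision":
                    payload["reported_at"] = _dts(payload["reported_at"])
                    store.collisions.append(CollisionRecord(**payload))
                else:  # pragma: no cover - forward compatibility guard
                    raise StoreError(f"unknown snapshot record kind {kind!r}")
        return store


def _line(kind: str, data: dict) -> str:
    return json.dumps({"kind": kind, "data": data},
                      ensure_ascii=False, sort_keys=True) + "\n"


def _ts(value: Optional[_dt.datetime]) -> Optional[str]:
    return value.isoformat() if value is not None else None


def _dts(value: Optional[str]) -> Optional[_dt.datetime]:
    return _dt.datetime.fromisoformat(value) if value else None


def _ssn_or_none(raw: Optional[str]) -> Optional[SSN]:
    if not raw:
        return None
    outcome = validate_ssn(raw)
    if not outcome.ok:
        raise StoreError(f"snapshot holds invalid SSN {raw!r}: {outcome.reason}")
    return outcome.ssn


def _traits_from_row(row: dict) -> IdentityTraits:
    def date_or_none(text):
        return parse_date(text) if text else None

    return IdentityTraits(
        first_name=row["first_name"],
        last_name=row["last_name"],
        birth_date=parse_date(row["birth_date"]),
        sex=row["sex"],
        middle_name=row.get("middle_name") or None,
        birth_place=row.get("birth_place") or None,
        native_country=row.get("native_country") or None,
        legal_address_line1=row.get("legal_address_line1") or None,
        legal_address_line2=row.get("legal_address_line2") or None,
        corr_address_line1=row.get("corr_address_line1") or None,
        corr_address_line2=row.get("corr_address_line2") or None,
        death_indicator=row.get("death_indicator") or None,
        death_date=date_or_none(row.get("death_date")),
        mobile_phone=row.get("mobile_phone") or None,
        email=row.get("email") or None,
    )
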