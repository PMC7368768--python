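"""Deterministic identity matching and the threshold-driven decision tree.

An incoming record is compared field-by-field against stored central
identities on the national identifier (SSN) and the four strict traits.
Each compared field carries a weight (percentage points summing to 100);
the match score is the sum of the weights of the fields that agree
exactly, so a score of 100 means every compared field matched. Name
comparison is diacritic-sensitive after whitespace/case normalization;
dates, sex and SSN compare by exact equality. When one side lacks an SSN,
the SSN field is excluded and the remaining weights are renormalized to
keep scores on the 0–100 scale.

Every admission or update event is routed through a decision tree keyed
to three thresholds (exact match 100, candidate ambiguity Δ = 1, keep 70,
transitory floor 50); the nine possible outcomes carry audit branch
labels a1, a2.1, a2.2, b1, c1.1, c1.2, d1.1, d1.2, e:

* creation events reconcile to a single exact-match candidate (a1),
  resolve multi-candidate ambiguity by the score gap Δ (a2.1 reconciles,
  a2.2 creates a new profile and flags a potential duplicate), and
  otherwise create a new central profile (b1);
* update events keep the reconciliation above 70 (central traits follow
  only in the reference workflow: c1.1 vs c1.2), park it for vigilance
  review between 50 and 70 (d1.1 reference / d1.2 otherwise), and below
  50 deactivate it and create a fresh profile (e).

Collision avoidance: automatic reconciliation of a *new* local record
additionally requires that the 100% score includes an SSN comparison.
A record presented without the national identifier therefore never
auto-attaches to an existing profile — it opens a new one, which identity
vigilance may later merge — because wrongly attaching records to another
person's profile (a collision) is the one error the system must never
make on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Optional

from .ssn import SSN
from .store import MPIStore, MPIError, Reconciliation
from .traits import IdentityTraits, ValidationReport, normalize_name, validate_traits

__all__ = [
    "MatchWeights",
    "Thresholds",
    "MatchResult",
    "MatchOutcome",
    "TraitValidationError",
    "match_score",
    "find_candidates",
    "process_identity_event",
    "DEFAULT_WEIGHTS",
    "DEFAULT_THRESHOLDS",
]

COMPARED_FIELDS = ("ssn", "last_name", "first_name", "birth_date", "sex")


class TraitValidationError(MPIError):
    """Raised when an event carries a rejected identity profile."""

    def __init__(self, report: ValidationReport):
        super().__init__("; ".join(report.reasons))
        self.report = report


@dataclass(frozen=True)
class MatchWeights:
    """Per-field weights in percentage points; must sum to 100.

    The defaults put the national identifier first (40) and split the
    remainder over the strict traits (last 20, first 20, birth date 15,
    sex 5) so that any single strict-trait discrepancy stays above the
    70-point keep threshold while a compound first-name + birth-date
    discrepancy lands in the 50–70 vigilance band.
    """

    ssn: float = 40.0
    last_name: float = 20.0
    first_name: float = 20.0
    birth_date: float = 15.0
    sex: float = 5.0

    def __post_init__(self):
        values = [self.ssn, self.last_name, self.first_name, self.birth_date, self.sex]
        if any(v <= 0 for v in values):
            raise ValueError("all match weights must be positive")
        if abs(sum(values) - 100.0) > 1e-9:
            raise ValueError("match weights must sum to 100")

    def weight(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class Thresholds:
    """Decision-tree thresholds, on the 0–100 score scale."""

    exact: float = 100.0
    delta: float = 1.0
    keep: float = 70.0
    transitory_low: float = 50.0
    candidate_floor: float = 50.0


DEFAULT_WEIGHTS = MatchWeights()
DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class MatchResult:
    """One candidate's score with the field-level agreement detail."""

    fid: Optional[str]
    score: float
    matched_fields: List[str] = field(default_factory=list)
    mismatched_fields: List[str] = field(default_factory=list)

    @property
    def ssn_compared(self) -> bool:
        return "ssn" in self.matched_fields or "ssn" in self.mismatched_fields


@dataclass
class MatchOutcome:
    """The action taken for one identity event, with its audit branch label."""

    action: str
    fid: str
    branch: str
    score: Optional[float] = None
    duplicate_case: Optional[int] = None
    reconciliation: Optional[Reconciliation] = None


def match_score(traits_a: IdentityTraits, ssn_a: Optional[SSN],
                traits_b: IdentityTraits, ssn_b: Optional[SSN],
                weights: MatchWeights = DEFAULT_WEIGHTS,
                fid: Optional[str] = None) -> MatchResult:
    """Score two identity records; symmetric in its two sides.

    The SSN is compared only when both sides carry one; otherwise it is
    excluded and the trait weights are renormalized to 100.
    """
    matched: List[str] = []
    mismatched: List[str] = []
    compare_ssn = ssn_a is not None and ssn_b is not None
    if compare_ssn:
        (matched if ssn_a.raw == ssn_b.raw else mismatched).append("ssn")
    for name in ("last_name", "first_name"):
        same = normalize_name(getattr(traits_a, name)) == normalize_name(getattr(traits_b, name))
        (matched if same else mismatched).append(name)
    (matched if traits_a.birth_date == traits_b.birth_date else mismatched).append("birth_date")
    (matched if traits_a.sex == traits_b.sex else mismatched).append("sex")

    total = sum(weights.weight(f) for f in matched + mismatched)
    gained = sum(weights.weight(f) for f in matched)
    score = 100.0 * gained / total if total else 0.0
    return MatchResult(fid=fid, score=score, matched_fields=matched,
                       mismatched_fields=mismatched)


def find_candidates(store: MPIStore, traits: IdentityTraits,
                    ssn: Optional[SSN] = None,
                    weights: MatchWeights = DEFAULT_WEIGHTS,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS) -> List[MatchResult]:
    """Retrieve and score candidate central identities for an incoming record.

    Candidates come from blocking buckets (exact SSN; diacritic-folded
    last name + birth date; folded first name + birth date; folded last
    name + folded first name), which together retrieve every profile that
    can score at or above the 50-point floor under the default weights.
    Results are sorted by descending score, ties broken by ascending FID.
    """
    results = []
    for fid in store.candidate_fids(traits, ssn):
        central = store.centrals[fid]
        result = match_score(traits, ssn, central.traits, central.ssn,
                             weights=weights, fid=fid)
        if result.score >= thresholds.candidate_floor:
            results.append(result)
    results.sort(key=lambda r: (-r.score, r.fid))
    return results


def _is_exact(result: MatchResult, thresholds: Thresholds) -> bool:
    return result.score >= thresholds.exact - 1e-9


def process_identity_event(store: MPIStore, domain_id: str, local_id: str,
                           record: Mapping[str, object], event: str = "CREATE",
                           weights: MatchWeights = DEFAULT_WEIGHTS,
                           thresholds: Thresholds = DEFAULT_THRESHOLDS) -> MatchOutcome:
    """Run one admission (CREATE) or modification (UPDATE) event.

    ``record`` is a raw trait map (Table-style columns, ``ssn`` included
    when known); it is validated before any store mutation, with the SSN
    mandatory only in the reference workflow. A CREATE for a (domain,
    local identifier) pair that is already reconciled is handled as an
    UPDATE, and vice versa, so replaying an identical admission is
    idempotent.
    """
    domain = store.get_domain(domain_id)
    report = validate_traits(record, require_ssn=(domain.kind == "REFERENCE"))
    if not report.accepted:
        raise TraitValidationError(report)
    traits, ssn = report.traits, report.ssn

    existing = store.active_reconciliation(domain_id, local_id)
    if existing is None:
        return _handle_create(store, domain, local_id, traits, ssn,
                              weights, thresholds)
    return _handle_update(store, domain, existing, traits, ssn,
                          weights, thresholds)


def _handle_create(store, domain, local_id, traits, ssn, weights, thresholds):
    candidates = find_candidates(store, traits, ssn, weights, thresholds)
    top = candidates[0] if candidates else None
    # Automatic attachment demands an exact match that includes the SSN.
    top_reconcilable = (top is not None and _is_exact(top, thresholds)
                        and top.ssn_compared)

    if top_reconcilable and len(candidates) == 1:
        rec = store.add_reconciliation(domain.domain_id, local_id, top.fid)
        return MatchOutcome(action="RECONCILED_EXISTING", fid=top.fid,
                            branch="a1", score=top.score, reconciliation=rec)

    if top_reconcilable and len(candidates) >= 2:
        delta = abs(top.score - candidates[1].score)
        if delta < thresholds.delta:
            # Ambiguous: create a new profile rather than risk a collision,
            # and hand the pair to identity vigilance.
            from .vigilance import flag_duplicate

            central = store.create_central_identity(traits, ssn=ssn)
            rec = store.add_reconciliation(domain.domain_id, local_id, central.fid)
            case = flag_duplicate(store, central.fid, top.fid, origin="algorithm")
            return MatchOutcome(action="CREATED_NEW_CENTRAL_DUPLICATE_FLAGGED",
                                fid=central.fid, branch="a2.2", score=top.score,
                                duplicate_case=case.case_id, reconciliation=rec)
        rec = store.add_reconciliation(domain.domain_id, local_id, top.fid)
        return MatchOutcome(action="RECONCILED_EXISTING", fid=top.fid,
                            branch="a2.1", score=top.score, reconciliation=rec)

    central = store.create_central_identity(traits, ssn=ssn)
    rec = store.add_reconciliation(domain.domain_id, local_id, central.fid)
    return MatchOutcome(action="CREATED_NEW_CENTRAL", fid=central.fid,
                        branch="b1", score=top.score if top else None,
                        reconciliation=rec)


def _handle_update(store, domain, rec, traits, ssn, weights, thresholds):
    master, _ = store.lookup(rec.fid)
    result = match_score(traits, ssn, master.traits, master.ssn, weights=weights)
    is_reference = domain.kind == "REFERENCE"
    now = store.clock()

    if result.score > thresholds.keep:
        rec.updated_at = now
        if is_reference:
            store.set_central_traits(master.fid, traits, ssn=ssn,
                                     note=f"reference update via {rec.local_id}")
            return MatchOutcome(action="KEPT_RECONCILIATION_CENTRAL_UPDATED",
                                fid=master.fid, branch="c1.1",
                                score=result.score, reconciliation=rec)
        return MatchOutcome(action="KEPT_RECONCILIATION", fid=master.fid,
                            branch="c1.2", score=result.score, reconciliation=rec)

    if result.score >= thresholds.transitory_low:
        rec.status = "TRANSITORILY_MODIFIED"
        rec.pending_traits = traits
        rec.pending_ssn = ssn
        rec.updated_at = now
        if is_reference:
            master.temporarily_modified = True
            master.audit_log.append((now.isoformat(), "TEMPORARILY_MODIFIED",
                                     rec.local_id))
            return MatchOutcome(action="TRANSITORILY_MODIFIED", fid=master.fid,
                                branch="d1.1", score=result.score,
                                reconciliation=rec)
        return MatchOutcome(action="TRANSITORILY_MODIFIED", fid=master.fid,
                            branch="d1.2", score=result.score, reconciliation=rec)

    rec.status = "DEACTIVATED"
    rec.updated_at = now
    central = store.create_central_identity(traits, ssn=ssn)
    new_rec = store.add_reconciliation(domain.domain_id, rec.local_id, central.fid)
    return MatchOutcome(action="DEACTIVATED_AND_CREATED", fid=central.fid,
                        branch="e", score=result.score, reconciliation=new_rec)
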