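"""End-to-end pipeline runs used for calibration and verification.

The headline experiment exercises the whole engine: generate a
multicultural population, ingest it through the reference workflow,
re-present a corrupted variant of each selected person from a secondary
domain, let the surveillance scan flag the resulting potential
duplicates, merge them with the injected ground-truth cause labels (the
synthetic stand-in for the human vigilance cell), and read the cause
mixture back from the vigilance report. With a large enough population
the reported cause percentages recover the injected mixture up to
multinomial sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

from .delta import DeltaRecord, IngestSummary, apply_delta
from .matching import process_identity_event
from .store import MPIStore
from .synth import (AnomalyConfig, PopulationConfig, generate_population,
                    inject_anomalies)
from .vigilance import (VigilanceStats, dismiss_case, merge_duplicates,
                        scan_potential_duplicates, vigilance_report)

__all__ = ["RecoveryResult", "anomaly_recovery_experiment"]

REFERENCE_DOMAIN = "ccss"
SECONDARY_DOMAIN = "hosp-a"


@dataclass
class RecoveryResult:
    """Outcome of one anomaly-recovery run."""

    n_population: int
    n_variants: int
    ingest: IngestSummary
    cases_flagged: int
    cases_merged: int
    cases_dismissed: int
    stats: VigilanceStats
    injected_mix: Dict[str, float]
    store: Optional[MPIStore] = None


def anomaly_recovery_experiment(n: int = 10_000, seed: int = 0,
                                fraction: float = 1.0,
                                cause_mix: Optional[Dict[str, float]] = None,
                                keep_store: bool = False) -> RecoveryResult:
    """Run the generate → ingest → corrupt → match → merge → report pipeline.

    All randomness (population draw, FID allocation, anomaly causes)
    derives from ``seed``. Each corrupted variant is admitted as a CREATE
    event from a secondary domain under a fresh local identifier; since
    no variant can produce an SSN-confirmed exact match, each opens a new
    central profile that the surveillance scan then pairs with its source
    (shared SSN, or identical strict traits for the identifier-less
    LOCAL_ID variants). Flagged pairs matching the injected ground truth
    are merged with their true cause; any incidental pair (homonym noise)
    is dismissed without a cause label.
    """
    store = MPIStore(seed=seed)
    store.register_domain(REFERENCE_DOMAIN, "REFERENCE", "national registry")
    store.register_domain(SECONDARY_DOMAIN, "SECONDARY", "hospital feed")

    pop_config = PopulationConfig(n=n, seed=seed)
    persons = generate_population(pop_config)
    records = [DeltaRecord(line_no=i + 2, row=p.row)
               for i, p in enumerate(persons)]
    ingest = apply_delta(store, records)

    anomaly_config = AnomalyConfig(fraction=fraction, seed=seed + 1,
                                   **({"cause_mix": dict(cause_mix)} if cause_mix else {}))
    variants = inject_anomalies(persons, anomaly_config)

    # FID of each person's registry profile, via the reference reconciliation.
    source_fid = {}
    for rec in store.reconciliations:
        if rec.domain_id == REFERENCE_DOMAIN and rec.status != "DEACTIVATED":
            source_fid[rec.local_id] = rec.fid

    truth: Dict[frozenset, tuple] = {}
    for idx, variant in enumerate(variants):
        outcome = process_identity_event(store, SECONDARY_DOMAIN,
                                         f"H{idx:08d}", variant.row,
                                         event="CREATE")
        src = source_fid[variant.source.ssn]
        if outcome.fid != src:
            truth[frozenset((src, outcome.fid))] = (src, outcome.fid,
                                                    variant.cause)

    scan_potential_duplicates(store)

    merged = dismissed = 0
    for case in list(store.duplicate_cases):
        if case.status != "POTENTIAL":
            continue
        entry = truth.get(case.pair)
        if entry is None:
            dismiss_case(store, case.case_id)
            dismissed += 1
        else:
            master, slave, cause = entry
            merge_duplicates(store, case.case_id, master=master, slave=slave,
                             cause=cause)
            merged += 1

    stats = vigilance_report(store)
    return RecoveryResult(
        n_population=n,
        n_variants=len(variants),
        ingest=ingest,
        cases_flagged=len(store.duplicate_cases),
        cases_merged=merged,
        cases_dismissed=dismissed,
        stats=stats,
        injected_mix=dict(anomaly_config.cause_mix),
        store=store if keep_store else None,
    )
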