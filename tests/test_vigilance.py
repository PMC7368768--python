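"""Duplicate lifecycle, master/slave merging, and vigilance statistics."""

import datetime as dt
import random

import pytest

from mpindex import (MPIStore, VigilanceError, dismiss_case, flag_duplicate,
                     merge_duplicates, report_collision, resolve_transitory,
                     scan_potential_duplicates, throughput_summary,
                     validate_traits, vigilance_report)
from mpindex.matching import process_identity_event

from conftest import TickClock, make_row


def add_profile(store, i):
    report = validate_traits(make_row(first=f"P{i}", ssn=True, seq=i),
                             require_ssn=True)
    return store.create_central_identity(report.traits, ssn=report.ssn).fid


class TestFlagAndDismiss:
    def test_flag_creates_potential_case(self, store):
        a, b = add_profile(store, 1), add_profile(store, 2)
        case = flag_duplicate(store, a, b, origin="algorithm")
        assert case.status == "POTENTIAL" and case.pair == {a, b}

    def test_same_fid_twice_refused(self, store):
        a = add_profile(store, 1)
        with pytest.raises(VigilanceError):
            flag_duplicate(store, a, a)

    def test_reflagging_open_pair_refused_with_case_reference(self, store):
        a, b = add_profile(store, 1), add_profile(store, 2)
        case = flag_duplicate(store, a, b)
        with pytest.raises(VigilanceError, match=str(case.case_id)):
            flag_duplicate(store, b, a)

    def test_dismissed_case_never_reopens(self, store):
        a, b = add_profile(store, 1), add_profile(store, 2)
        case = dismiss_case(store, flag_duplicate(store, a, b).case_id)
        assert case.status == "DISMISSED"
        with pytest.raises(VigilanceError):
            merge_duplicates(store, case.case_id, master=a, slave=b)


class TestMerge:
    def test_merge_repoints_lookup_and_reconciliations(self, store):
        a, b = add_profile(store, 1), add_profile(store, 2)
        store.add_reconciliation("hospA", "L1", b)
        case = flag_duplicate(store, a, b)
        merge_duplicates(store, case.case_id, master=a, slave=b,
                         cause="MARITAL_NAME")
        assert store.lookup(b)[0].fid == a
        assert store.active_reconciliation("hospA", "L1").fid == a
        assert store.get_central(b).status == "MERGED_SLAVE"
        assert case.cause == "MARITAL_NAME"

    def test_master_must_belong_to_case_and_be_active(self, store):
        a, b, c = (add_profile(store, i) for i in range(3))
        case = flag_duplicate(store, a, b)
        with pytest.raises(VigilanceError):
            merge_duplicates(store, case.case_id, master=c, slave=b)
        merge_duplicates(store, case.case_id, master=b, slave=a)
        # a is now a slave: it cannot serve as master of a new case
        case2 = flag_duplicate(store, b, c)
        merge_duplicates(store, case2.case_id, master=c, slave=b)
        assert store.lookup(a)[0].fid == c

    def test_random_merge_sequences_preserve_fid_partition(self):
        """After arbitrary merges: slaves resolve to active masters, the
        merge graph is acyclic, and no FID is lost."""
        rng = random.Random(7)
        store = MPIStore(seed=1, clock=TickClock())
        store.register_domain("ccss", "REFERENCE")
        store.register_domain("hospA", "SECONDARY")
        all_fids = [add_profile(store, i) for i in range(60)]
        for _ in range(45):
            active = [f for f in all_fids
                      if store.centrals[f].status == "ACTIVE"]
            if len(active) < 2:
                break
            a, b = rng.sample(active, 2)
            try:
                case = flag_duplicate(store, a, b)
            except VigilanceError:
                continue
            merge_duplicates(store, case.case_id, master=a, slave=b)
        active = {f for f in all_fids if store.centrals[f].status == "ACTIVE"}
        slaves = {f for f in all_fids if store.centrals[f].status == "MERGED_SLAVE"}
        assert active | slaves == set(all_fids) and not active & slaves
        for fid in all_fids:
            master, path = store.lookup(fid)  # terminates => acyclic
            assert master.status == "ACTIVE"
            assert len(path) == len(set(path))


class TestResolveTransitory:
    def _park(self, store, domain, local):
        row = make_row(ssn=True)
        process_identity_event(store, "ccss", row["ssn"], row, "CREATE")
        if domain != "ccss":
            process_identity_event(store, domain, local, row, "CREATE")
        drift = dict(row)
        drift["first_name"], drift["birth_date"] = "Pauline", "04/05/1981"
        key = row["ssn"] if domain == "ccss" else local
        out = process_identity_event(store, domain, key, drift, "UPDATE")
        assert out.action == "TRANSITORILY_MODIFIED"
        return row, key

    def test_accept_reference_applies_pending_modification(self, store):
        row, key = self._park(store, "ccss", None)
        rec = resolve_transitory(store, "ccss", key, "ACCEPT")
        assert rec.status == "VALID" and rec.pending_traits is None
        master, _ = store.lookup(rec.fid)
        assert master.traits.first_name == "Pauline"
        assert not master.temporarily_modified

    def test_revert_discards_pending_modification(self, store):
        row, key = self._park(store, "hospA", "L9")
        rec = resolve_transitory(store, "hospA", "L9", "REVERT")
        assert rec.status == "VALID"
        assert store.lookup(rec.fid)[0].traits.first_name == row["first_name"]

    def test_resolve_requires_transitory_state(self, store):
        row = make_row(ssn=True)
        process_identity_event(store, "ccss", row["ssn"], row, "CREATE")
        with pytest.raises(VigilanceError):
            resolve_transitory(store, "ccss", row["ssn"], "ACCEPT")


class TestScan:
    def test_scan_pairs_shared_ssn_and_identical_traits(self, store):
        row = make_row(ssn=True)
        a = process_identity_event(store, "ccss", row["ssn"], row, "CREATE").fid
        bare = dict(row); bare["ssn"] = ""
        b = process_identity_event(store, "hospA", "L1", bare, "CREATE").fid
        opened = scan_potential_duplicates(store)
        assert {frozenset(c.pair) for c in opened} == {frozenset((a, b))}
        assert scan_potential_duplicates(store) == []  # idempotent

    def test_clean_store_scan_opens_nothing(self, store):
        for i in range(10):
            row = make_row(first=f"P{i}", birth=f"0{i % 9 + 1}/03/1970",
                           ssn=True, seq=i)
            process_identity_event(store, "ccss", row["ssn"], row, "CREATE")
        assert scan_potential_duplicates(store) == []


class TestReports:
    def test_cause_distribution_matches_construction(self, store):
        """29 + 29 + 20 + 22 merged cases reproduce their percentages exactly."""
        mix = [("MARITAL_NAME", 29), ("SPELLING", 29), ("LOCAL_ID", 20),
               ("OTHER", 22)]
        i = 0
        for cause, count in mix:
            for _ in range(count):
                a, b = add_profile(store, i), add_profile(store, i + 1)
                i += 2
                case = flag_duplicate(store, a, b)
                merge_duplicates(store, case.case_id, master=a, slave=b,
                                 cause=cause)
        stats = vigilance_report(store)
        assert stats.merged_count == 100
        for cause, count in mix:
            assert stats.cause_distribution[cause] == pytest.approx(count)

    def test_anomalies_per_day_rounds_to_published_rate(self, store):
        """426 anomalies over a 365-day year -> 1.2 per day."""
        for i in range(426):
            a, b = add_profile(store, 2 * i), add_profile(store, 2 * i + 1)
            flag_duplicate(store, a, b)
        stats = vigilance_report(store, period=(dt.date(2018, 1, 1),
                                                dt.date(2018, 12, 31)))
        assert stats.anomalies_total == 426
        assert round(stats.anomalies_per_day, 1) == 1.2

    def test_empty_store_report_zeroes(self, store):
        stats = vigilance_report(store)
        assert stats.anomalies_total == 0 and stats.cause_distribution == {}

    def test_throughput_summary_headline_figures(self):
        summary = throughput_summary(profiles_retrieved=180_266,
                                     profiles_total=2_278_003,
                                     anomalies=426, days=365,
                                     daily_treated=400)
        assert round(summary["retrieved_share_pct"]) == 8
        assert round(summary["anomalies_per_day"], 1) == 1.2
        assert round(summary["anomaly_ratio_pct"], 1) == 0.3


class TestCollisions:
    def test_report_appends_and_requires_known_fid(self, store):
        fid = add_profile(store, 1)
        report_collision(store, fid, reporter="hospA", note="two people")
        assert len(store.collisions) == 1
        from mpindex import UnknownFID
        with pytest.raises(UnknownFID):
            report_collision(store, "0000000000", reporter="hospA")

    def test_exact_match_policy_yields_zero_collisions(self, store):
        """A store driven only by the matcher never assigns one profile to
        two people: the collision log stays empty."""
        from mpindex import PopulationConfig, generate_population

        persons = generate_population(PopulationConfig(n=200, seed=4))
        for person in persons:
            process_identity_event(store, "ccss", person.ssn, person.row,
                                   "CREATE")
        assert len(store.collisions) == 0
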