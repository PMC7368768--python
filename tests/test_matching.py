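"""Deterministic matcher: scores, candidate retrieval, the decision tree.

The randomized trials check the engine against an independently written
brute-force oracle that scores the incoming record versus every stored
profile and applies the published decision table directly.
"""

import random

import pytest

from mpindex import (MPIStore, PopulationConfig, find_candidates,
                     generate_population, match_score, process_identity_event,
                     validate_traits)

from conftest import TickClock, make_row


# --- independent brute-force oracle ---------------------------------------

_W = {"ssn": 40.0, "last_name": 20.0, "first_name": 20.0,
      "birth_date": 15.0, "sex": 5.0}


def _norm(text):
    return " ".join(str(text).split()).lower()


def oracle_score(row, central):
    """Field-by-field weighted agreement, written independently of the engine."""
    got = total = 0.0
    in_ssn = str(row.get("ssn") or "").strip()
    c_ssn = central.ssn.raw if central.ssn else None
    ssn_compared = bool(in_ssn) and c_ssn is not None
    if ssn_compared:
        total += _W["ssn"]
        got += _W["ssn"] if in_ssn == c_ssn else 0.0
    for name in ("last_name", "first_name"):
        total += _W[name]
        got += _W[name] if _norm(row[name]) == _norm(getattr(central.traits, name)) else 0.0
    total += _W["birth_date"]
    d, m, y = (int(p) for p in row["birth_date"].split("/"))
    b = central.traits.birth_date
    got += _W["birth_date"] if (b.day, b.month, b.year) == (d, m, y) else 0.0
    total += _W["sex"]
    got += _W["sex"] if row["sex"] == central.traits.sex else 0.0
    return 100.0 * got / total, ssn_compared


def oracle_create(store, row):
    scored = []
    for fid, central in store.centrals.items():
        if central.status != "ACTIVE":
            continue
        score, ssn_compared = oracle_score(row, central)
        if score >= 50.0:
            scored.append((score, fid, ssn_compared))
    scored.sort(key=lambda t: (-t[0], t[1]))
    if scored and scored[0][0] >= 100.0 - 1e-9 and scored[0][2]:
        if len(scored) == 1:
            return ("a1", scored[0][1])
        if abs(scored[0][0] - scored[1][0]) < 1.0:
            return ("a2.2", None)
        return ("a2.1", scored[0][1])
    return ("b1", None)


def oracle_update(store, rec, row, reference):
    fid = rec.fid
    while store.centrals[fid].status == "MERGED_SLAVE":
        fid = store.centrals[fid].merged_into
    score, _ = oracle_score(row, store.centrals[fid])
    if score > 70.0:
        return ("c1.1" if reference else "c1.2", fid)
    if score >= 50.0:
        return ("d1.1" if reference else "d1.2", fid)
    return ("e", None)


# --- unit examples --------------------------------------------------------

def parsed(row, require_ssn=False):
    report = validate_traits(row, require_ssn=require_ssn)
    assert report.accepted, report.reasons
    return report.traits, report.ssn


class TestMatchScore:
    def test_identical_records_score_100(self):
        t, s = parsed(make_row(ssn=True))
        result = match_score(t, s, t, s)
        assert result.score == 100.0
        assert set(result.matched_fields) == {"ssn", "last_name", "first_name",
                                              "birth_date", "sex"}

    def test_differing_ssn_scores_60(self):
        t, s1 = parsed(make_row(ssn=True, seq=1))
        _, s2 = parsed(make_row(ssn=True, seq=2))
        assert match_score(t, s1, t, s2).score == 60.0

    def test_sex_only_mismatch_scores_95(self):
        ta, s = parsed(make_row(sex="F", ssn=True))
        tb, _ = parsed(make_row(sex="M"))
        assert match_score(ta, s, tb, s).score == 95.0

    def test_missing_ssn_renormalizes(self):
        ta, s = parsed(make_row(ssn=True))
        tb, _ = parsed(make_row(last="Other"))
        # ssn excluded: (20+15+5)/60 of the scale
        result = match_score(ta, s, tb, None)
        assert result.score == pytest.approx(100 * 40 / 60)
        assert not result.ssn_compared

    def test_symmetric(self):
        ta, sa = parsed(make_row(ssn=True))
        tb, sb = parsed(make_row(first="Other", ssn=True, seq=5))
        assert match_score(ta, sa, tb, sb).score == match_score(tb, sb, ta, sa).score

    def test_diacritics_are_significant(self):
        ta, _ = parsed(make_row(last="Müller"))
        tb, _ = parsed(make_row(last="Muller"))
        assert "last_name" in match_score(ta, None, tb, None).mismatched_fields


class TestFindCandidates:
    def test_exact_twin_found(self, store):
        row = make_row(ssn=True)
        process_identity_event(store, "ccss", row["ssn"], row, "CREATE")
        t, s = parsed(row)
        results = find_candidates(store, t, s)
        assert len(results) == 1 and results[0].score == 100.0

    def test_empty_store_empty_list(self):
        empty = MPIStore(seed=0)
        t, s = parsed(make_row(ssn=True))
        assert find_candidates(empty, t, s) == []

    def test_blocking_loses_no_candidate_above_floor(self, store):
        """Full-scan scoring of the whole store agrees with the blocked
        retrieval, including diacritic-variant and no-SSN incomings."""
        persons = generate_population(PopulationConfig(n=300, seed=9,
                                                       homonym_rate=0.2))
        for i, person in enumerate(persons):
            process_identity_event(store, "ccss", person.ssn, person.row, "CREATE")
        rng = random.Random(1)
        for _ in range(60):
            row = dict(rng.choice(persons).row)
            mutation = rng.choice(["none", "drop_ssn", "typo", "birth"])
            if mutation == "drop_ssn":
                row["ssn"] = ""
            elif mutation == "typo":
                row["last_name"] = row["last_name"] + "x"
            elif mutation == "birth":
                row["birth_date"] = "15/06/1975"
            t, s = parsed(row)
            got = [(r.fid, round(r.score, 6)) for r in find_candidates(store, t, s)]
            expected = []
            for fid, central in store.centrals.items():
                if central.status != "ACTIVE":
                    continue
                score, _ = oracle_score(row, central)
                if score >= 50.0:
                    expected.append((fid, round(score, 6)))
            expected.sort(key=lambda p: (-p[1], p[0]))
            assert got == expected


class TestDecisionTree:
    def test_all_nine_branches_with_exact_actions(self, store):
        """A constructed event suite reaches every audit label with the
        action the decision table specifies."""
        seen = {}

        # b1: empty store, new registry identity
        p = make_row(first="Aline", last="Faber", birth="03/04/1980",
                     sex="F", ssn=True, seq=1)
        out = process_identity_event(store, "ccss", p["ssn"], p, "CREATE")
        assert out.action == "CREATED_NEW_CENTRAL"
        seen["b1"] = out
        fid0 = out.fid

        # a1: same person admitted by the hospital
        out = process_identity_event(store, "hospA", "L1", p, "CREATE")
        assert out.action == "RECONCILED_EXISTING" and out.fid == fid0
        seen["a1"] = out

        # a2.1: exact match plus a lower-scoring homonym candidate
        q = make_row(first="Aline", last="Faber", birth="03/04/1980",
                     sex="F", ssn=True, seq=2)  # same traits, other SSN
        process_identity_event(store, "ccss", q["ssn"], q, "CREATE")
        out = process_identity_event(store, "hospA", "L2", p, "CREATE")
        assert out.action == "RECONCILED_EXISTING" and out.fid == fid0
        seen["a2.1"] = out

        # a2.2: two exact candidates (an existing duplicated profile)
        t, s = parsed(p)
        store.create_central_identity(t, ssn=s)  # second profile, same SSN
        out = process_identity_event(store, "hospA", "L3", p, "CREATE")
        assert out.action == "CREATED_NEW_CENTRAL_DUPLICATE_FLAGGED"
        assert out.duplicate_case is not None
        seen["a2.2"] = out

        # c1.1 / c1.2: minor modification (sex), score 95 > 70
        mod = dict(p); mod["sex"] = "A"
        out = process_identity_event(store, "ccss", p["ssn"], mod, "UPDATE")
        assert out.action == "KEPT_RECONCILIATION_CENTRAL_UPDATED"
        assert store.get_central(out.fid).traits.sex == "A"
        seen["c1.1"] = out
        mod2 = dict(mod); mod2["sex"] = "F"
        out = process_identity_event(store, "hospA", "L1", mod2, "UPDATE")
        assert out.action == "KEPT_RECONCILIATION"
        assert store.lookup(out.fid)[0].traits.sex == "A"  # central untouched
        seen["c1.2"] = out

        # d1.1 / d1.2: first name + birth date diverge, score 65 in [50, 70]
        tm = dict(mod)
        tm["first_name"], tm["birth_date"] = "Pauline", "04/05/1981"
        out = process_identity_event(store, "ccss", p["ssn"], tm, "UPDATE")
        assert out.action == "TRANSITORILY_MODIFIED"
        assert store.get_central(out.fid).temporarily_modified
        seen["d1.1"] = out
        tm2 = dict(mod2)
        tm2["first_name"], tm2["birth_date"] = "Pauline", "04/05/1981"
        out = process_identity_event(store, "hospA", "L1", tm2, "UPDATE")
        assert out.action == "TRANSITORILY_MODIFIED"
        assert out.reconciliation.status == "TRANSITORILY_MODIFIED"
        seen["d1.2"] = out

        # e: all three names/dates diverge, score 45 < 50
        far = dict(p)
        far["first_name"], far["last_name"], far["birth_date"] = (
            "Robert", "Wagner", "09/10/1955")
        out = process_identity_event(store, "hospA", "L2", far, "UPDATE")
        assert out.action == "DEACTIVATED_AND_CREATED"
        seen["e"] = out

        assert {o.branch for o in seen.values()} == {
            "a1", "a2.1", "a2.2", "b1", "c1.1", "c1.2", "d1.1", "d1.2", "e"}
        for label, outcome in seen.items():
            assert outcome.branch == label

    def test_replaying_identical_create_is_idempotent(self, store):
        row = make_row(ssn=True)
        first = process_identity_event(store, "ccss", row["ssn"], row, "CREATE")
        n_centrals = len(store.centrals)
        again = process_identity_event(store, "ccss", row["ssn"], row, "CREATE")
        assert again.branch == "c1.1" and again.score == 100.0
        assert again.fid == first.fid
        assert len(store.centrals) == n_centrals

    def test_no_ssn_admission_never_autoreconciles(self, store):
        """Collision avoidance: an identifier-less record with identical
        traits opens a new profile instead of attaching to an existing one."""
        row = make_row(ssn=True)
        keep = process_identity_event(store, "ccss", row["ssn"], row, "CREATE")
        bare = dict(row); bare["ssn"] = ""
        out = process_identity_event(store, "hospA", "X1", bare, "CREATE")
        assert out.branch == "b1" and out.fid != keep.fid

    def test_fid_count_never_decreases(self, store):
        rng = random.Random(2)
        low = 0
        for i in range(60):
            row = make_row(first=rng.choice(["Ana", "Eva"]),
                           last=rng.choice(["Silva", "Weber", "Faber"]),
                           ssn=True, seq=rng.randrange(50))
            process_identity_event(store, rng.choice(["ccss", "hospA"]),
                                   f"L{rng.randrange(20)}", row,
                                   rng.choice(["CREATE", "UPDATE"]))
            assert len(store.centrals) >= low
            low = len(store.centrals)

    def test_malformed_traits_error_before_mutation(self, store):
        from mpindex import TraitValidationError

        before = len(store.centrals)
        with pytest.raises(TraitValidationError):
            process_identity_event(store, "ccss", "X", make_row(last=""), "CREATE")
        assert len(store.centrals) == before


class TestOracleEquivalence:
    def test_engine_agrees_with_brute_force_on_random_events(self):
        """Branch and target FID agree with the full-scan oracle across
        randomized admission/update streams on small stores."""
        rng = random.Random(123)
        n_events = 0
        for trial in range(10):
            store = MPIStore(seed=trial, clock=TickClock())
            store.register_domain("ccss", "REFERENCE")
            store.register_domain("hospA", "SECONDARY")
            persons = generate_population(
                PopulationConfig(n=80, seed=trial, homonym_rate=0.15))
            for person in persons:
                process_identity_event(store, "ccss", person.ssn,
                                       person.row, "CREATE")
            local = 0
            for _ in range(100):
                n_events += 1
                row = dict(rng.choice(persons).row)
                mutation = rng.choice(["none", "none", "drop_ssn", "typo",
                                       "birth", "marital", "far"])
                if mutation == "drop_ssn":
                    row["ssn"] = ""
                elif mutation == "typo":
                    row["first_name"] = row["first_name"][:-1] + "x"
                elif mutation == "birth":
                    row["birth_date"] = "15/06/1975"
                elif mutation == "marital":
                    row["last_name"] = "Remplace"
                elif mutation == "far":
                    row["first_name"], row["last_name"] = "Zoe", "Zimmer"
                    row["birth_date"] = "01/02/1933"

                if rng.random() < 0.5 or not row["ssn"]:  # reference needs SSN
                    local += 1
                    expected = oracle_create(store, row)
                    out = process_identity_event(store, "hospA",
                                                 f"N{trial}-{local}", row,
                                                 "CREATE")
                else:
                    key = rng.choice(persons).ssn
                    rec = store.active_reconciliation("ccss", key)
                    if rec is None:
                        continue
                    expected = oracle_update(store, rec, row, reference=True)
                    out = process_identity_event(store, "ccss", key, row,
                                                 "UPDATE")
                assert out.branch == expected[0], (trial, mutation)
                if expected[1] is not None:
                    assert out.fid == expected[1]
        assert n_events >= 1000
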