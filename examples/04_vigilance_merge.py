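"""Duplicate detection and master/slave merging.

A person registered by the national feed is re-admitted by a hospital
under her marital name: the exact-match rule opens a second profile, the
surveillance scan flags the pair (shared national identifier), and the
vigilance cell merges them. Any further lookup of the slave resolves to
the master.
"""

from mpindex import (MPIStore, merge_duplicates, process_identity_event,
                     scan_potential_duplicates, vigilance_report)

store = MPIStore(seed=3)
store.register_domain("ccss", "REFERENCE")
store.register_domain("hosp-a", "SECONDARY")

maiden = {"first_name": "Hélène", "last_name": "Lefèvre",
          "birth_date": "12/06/1978", "sex": "F", "ssn": "1978061200229"}
registry = process_identity_event(store, "ccss", maiden["ssn"], maiden, "CREATE")
married = dict(maiden, last_name="Moreau")
hospital = process_identity_event(store, "hosp-a", "H001", married, "CREATE")
print(f"registry profile {registry.fid} (branch {registry.branch}); "
      f"hospital admission opened {hospital.fid} (branch {hospital.branch})")

cases = scan_potential_duplicates(store)
print(f"surveillance scan flagged {len(cases)} pair(s): "
      f"{cases[0].fid_a} / {cases[0].fid_b}")

merge_duplicates(store, cases[0].case_id, master=registry.fid,
                 slave=hospital.fid, cause="MARITAL_NAME")
master, path = store.lookup(hospital.fid)
print(f"lookup of slave {hospital.fid} resolves to master {master.fid} "
      f"via path {path}")

stats = vigilance_report(store)
print(f"merged cases: {stats.merged_count}, cause distribution: "
      f"{ {k: v for k, v in stats.cause_distribution.items() if v} }")
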