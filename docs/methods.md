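# Methods

This note documents the models, parameters and design choices behind
`mpindex`, in the order a reader meets them: profile validation and
identifiers, the matching score and decision tree, the federated store,
identity vigilance, ingestion, and the synthetic population that drives
the end-to-end experiments.

## Identity profiles and validation

A profile is the national trait chart: four mandatory *strict* traits
(first name, last name, birth date `DD/MM/YYYY`, sex ∈ {M, F, A}),
optional extended traits (birth place, ISO 3166-1 alpha-3 native
country, two two-line addresses, death indicator and date) and
complementary traits (mobile phone, e-mail), each with a maximum length
(names 100/70/70 characters, e-mail 20 — kept as chartered even though
20 is tight for real addresses). All text must be ISO-LATIN-1
representable, the encoding of the national feed. Validation is total:
any raw map yields a report with one coded reason per violation
(`MISSING_STRICT_TRAIT:<field>`, `INVALID_DATE:<field>`,
`FIELD_TOO_LONG:<field>`, `ENCODING:<field>`, `INVALID_SSN:<subcode>`,
…), never an exception, so ingestion can count rejections instead of
aborting. Sex `A` participates in matching exactly like M and F. The
death indicator accepts any single character; no controlled vocabulary
is imposed.

An SSN whose embedded birth date disagrees with the birth-date trait is
a *warning* routed to vigilance, not a rejection: the trait may be the
corrected value while the identifier is immutable.

## Identifiers

**SSN.** `YYYYMMDDSSSC₁C₂`. The two control algorithms are not fixed by
the published description ("two separate algorithms"); this package
adopts the national-number convention of a Luhn check digit over
positions 1–11 followed by a Verhoeff check digit over positions 1–12
(C₁ included). Both are implemented from their definitions and both are
swappable via the `algorithms` argument. Luhn catches every single-digit
substitution in its span, Verhoeff every substitution in its own
(including C₁), and C₂ protects itself, so the pair detects 100 % of
single-digit errors — verified exhaustively over all 13 × 9 mutations of
1,000 generated identifiers.

**FID.** A 10-digit zero-padded decimal string drawn uniformly by
rejection sampling from a seedable RNG; uniqueness is enforced per
store. Leading digits are uniform (chi-square at n = 100,000, α = 0.01).

## Matching score

Weighted exact agreement over five fields with default weights SSN 40,
last name 20, first name 20, birth date 15, sex 5 (percentage points,
sum 100). Name comparison trims, collapses whitespace and lower-cases
but **keeps diacritics** — "Müller" ≠ "Muller" for scoring. Dates, sex
and SSN compare by equality. If either side lacks an SSN the field is
excluded and the remaining weights are renormalized to 100.

The defaults were chosen so that, with the SSN present, every decision
band is reachable by a realistic error pattern: any single strict-trait
discrepancy stays above 70 (score 80–95), a compound first-name +
birth-date discrepancy lands at 65 (inside the 50–70 review band), and
an unrelated record with a shared SSN falls to 45 (< 50). Without an
SSN the renormalized scale compresses: a single name discrepancy then
scores 66.7 and is parked for review rather than kept — deliberately
conservative for identifier-less sources.

## Candidate retrieval (blocking)

Candidates come from the union of four hash buckets over active
profiles: exact SSN; (diacritic-folded last name, birth date);
(folded first name, birth date); (folded last name, folded first name).
Folding maps only the five accented vowels to their base letters and is
used for retrieval keys only, never applied to stored traits. Under the
default weights these keys are complete above the 50-point candidate
floor: any pair scoring ≥ 50 must share the SSN, or two of
{last name, first name, birth date}, each of which hits a bucket. The
property is checked against a brute-force full scan in the tests.
Ties in the candidate ranking break by ascending FID for determinism.

## Decision tree

Thresholds: exact = 100, ambiguity gap Δ = 1, keep = 70, review floor =
50; all configurable, defaults as published. For an admission with no
prior reconciliation in the domain: a single exact candidate reconciles
(a1); two or more candidates with the top at 100 reconcile to the best
when the gap to the runner-up exceeds Δ (a2.1) and otherwise open a new
profile with a flagged potential duplicate (a2.2, collision avoidance);
any top score below 100 opens a new profile (b1). A gap of exactly Δ
routes to a2.1; under integer default weights the gap between a 100 and
the next candidate is 0 or ≥ 5, so the tie-break is inert. For a
modification event the score is computed against the reconciled central
identity (resolved through merges): > 70 keeps the reconciliation, with
central traits following only in the reference workflow (c1.1 vs c1.2);
50–70 marks it transitorily modified with the incoming record held as a
pending modification for the vigilance cell (d1.2; the reference
workflow additionally marks the central profile temporarily modified,
d1.1); < 50 deactivates the link and opens a fresh profile (e). A CREATE
event on an already-reconciled local identifier is handled as UPDATE
(replay is idempotent), and an UPDATE without one as CREATE.

One rule is stricter than pure renormalization: **automatic attachment
at admission requires the 100 % score to include an SSN comparison.** A
record presented without the national identifier — however perfect its
traits — opens a new profile instead of reconciling. Rationale: with
renormalization alone, an identifier-less record with matching traits
would always auto-attach, making a collision (records of two homonymous
people fused onto one profile) possible from a single keystroke-poor
source, and making duplicates caused by divergent local identifiers
impossible to represent at all. The engine therefore trades automatic
convenience for collision safety and lets vigilance merge the resulting
duplicate, which mirrors how such pairs are actually resolved — by a
human cell with more context than four traits.

## Federated store

In-memory dictionaries with incremental blocking indexes; persistence is
a deterministic JSON-lines snapshot (sorted keys, ISO timestamps) whose
export → import → export round trip is byte-identical. Every profile keeps
an append-only audit log. Timestamps come from an injectable clock
(default wall clock; tests inject a ticking counter). Exactly one
REFERENCE domain may exist; SECONDARY domains produce longitudinal
reconciliations, CONSUMER domains transversal ones, and consumers never
modify central traits. Deactivated reconciliations are history: they are
never reactivated, and at most one non-deactivated link exists per
(domain, local identifier).

## Identity vigilance

Potential duplicate cases are opened by the matcher (a2.2) or by a
surveillance scan that pairs active profiles sharing an SSN or identical
strict traits; repeated scans are idempotent. A case is closed exactly
once: merged (master/slave; the slave profile is deactivated, points to
its master, and its reconciliations are re-pointed) or dismissed. Merge
chains stay acyclic and every lookup resolves to an active master; the
master keeps its own traits, the slave's remain readable on the slave
record. Cause labels (MARITAL_NAME, SPELLING, LOCAL_ID, OTHER) are
assigned at merge time by the operator — in synthetic runs, the injected
ground truth. The vigilance report counts cases opened/closed in a
period, computes anomalies per day over the period's day count, and the
cause distribution in percent over cases closed with a cause. Collisions
are only logged, never auto-resolved.

## Delta ingestion

Semicolon-separated CSV, ISO-LATIN-1, mandatory header naming the chart
columns, dates `DD/MM/YYYY`; an optional `status` column is filtered on
when present (non-`valid` rows are counted as rejected with reason
`AFFILIATION_STATUS`). Malformed rows are reported with line numbers and
skipped. In the reference domain the local identifier is the SSN itself,
which makes the operation inference natural: an SSN already reconciled
there is an UPDATE, anything else a CREATE. Every record passes full
validation (SSN mandatory in this workflow) before reaching the matcher;
the summary always satisfies read = created + updated + rejected. A dry
run executes against a deep copy of the store, producing the summary a
real run would, with no mutation.

## Synthetic population

Embedded per-nationality name pools (Portuguese, French, Italian,
Belgian, German, Luxembourgish, other-EU, non-EU; roughly 25–30 names
each, deliberately diacritic-rich, all ISO-LATIN-1) stand in for real
name dictionaries. The default nationality mix uses the published
community shares verbatim (PT .33, FR .16, IT .08, BE .07, DE .05,
other-EU .16, non-EU .15 — the caption's base population is ambiguous,
so the mix is a configurable default, not a demographic claim). Birth
dates are uniform over 1920–2005; sex is drawn 49.5/49.5/1 over M/F/A;
5 % homonym pressure reuses an existing name pair and 8 % of surnames
are hyphenated compounds, exercising the ambiguity branches. SSN
sequences count up per birth date, so identifiers are unique by
construction and every generated record is validator-clean.

Anomaly injection corrupts a configured fraction of the population, one
variant per selected person, with causes drawn from the default mixture
29/29/20/22 %: a spouse surname from the same pool (MARITAL_NAME), a
single-character typo or diacritic drop (SPELLING, always edit distance
1), the identical record without SSN from another domain (LOCAL_ID), or
an adjacent-digit transposition of the birth date constrained to remain
a valid past date (OTHER). Variants carry their true label and source.

What the generator does **not** emulate: realistic name-frequency
distributions, correlated household addresses, migration and mortality
dynamics, multi-error records, or free-text noise in extended traits.
Passing end-to-end tests therefore demonstrate the engine's mechanics
under the stated error taxonomy, not linkage performance on real
registries.

## Problem sizes and the headline experiment

The end-to-end experiment generates 10,000 identities, corrupts all of
them (fraction 1.0, i.e. 10,000 corrupted pairs), ingests originals
through the reference workflow and variants as secondary-domain
admissions, scans, merges with ground-truth causes, and reads the cause
shares from the vigilance report; recovered percentages are compared to
the injected mixture within binomial 99 % confidence intervals at
n = 10,000 (half-width ≈ 1.2 points at p ≈ 0.29). Randomized
property checks use 1,000 events against stores of ≤ 200 profiles for
the brute-force oracle comparison, 100,000 allocations for FID
uniformity, and 117,000 mutants for check-digit coverage. These sizes
were chosen so the entire suite runs comfortably on a single CPU while
keeping every statistical check at its stated confidence level.

## Known limitations

* Deterministic exact matching only — no probabilistic (Fellegi–Sunter)
  weights, phonetic codes or edit-distance similarity by design; a
  spelling error always costs the full field weight.
* Single-writer store; no concurrency or network API.
* Merged slaves are terminal: un-merge is not supported, and neither is
  reactivating a deactivated reconciliation.
* The reference lock is binary (reference vs everyone else); finer
  per-domain modification rights are out of scope.
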