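# Methods

## The representation

The package models documented data-use permissions as *policy-status
codes*: one OID per combination of a policy with one of three status
labels (`valid`, `not valid`, `unknown`). A *policy* is either a module of
a versioned consent template (a self-contained statement with an opt-in
decision) or a regulatory provision (e.g. a state hospital act permitting
intramural research); regulatory policies carry no template version and
are allocated under a sibling code system
(`2.16.840.1.113883.3.1937.777.24.5.2`) rather than the template's system
(`…24.5.1`).

Three data elements are mandatory on every record and enforced at
construction: the status (inside the code), the template version (inside
the policy reference), and the validity start date. The validity period is
a closed calendar-date interval; the end is optional (absent = open-ended).
Dates are timezone-free calendar days — the transported formats carry day
precision only — while the optional `recorded_at` provenance timestamp is
UTC.

### Allocation rules

Codes are consecutive children of the code-system OID: modules in template
order, labels in the fixed order `valid` (1), `not valid` (2), `unknown` (3).
The order of labels within a module is normative in this package (the
upstream registry convention is not machine-readable); what matters for
interoperability is that the allocation is deterministic, gapless, and
bijective between (policy, status) pairs and OIDs — all three are tested
properties. Codes are allocated per (policy, status) pair, not per
(policy, answer-text, status) triple: only pair-level codes are exchanged
between systems, and the answer text is recoverable from the template.
`unknown` is a registrable code (three codes per module) even though the
published status mappings never produce it: it completes the value set for
contexts that must *state* the absence of documentation.

Each module gets one value set containing exactly its three codes; the
value-set description carries the template version so revisions are
distinguishable.

## Dialects

* **FHIR Consent (R4 v4.0.0 / R3 v3.0.1, JSON).** Policy-status codes
  travel as `policy` URIs (written in the registry-lookup `RetrieveCode`
  spelling; bare OIDs and `urn:oid:` URNs are also accepted on read), the
  patient as `patient.identifier`, the period as `provision.period` (R4)
  or the resource-root `period` (R3 — Release 3 has no `provision`
  backbone, so the root period is the release-appropriate location). R4
  resources carry `scope` = `consentscope/patient-privacy`; R3 resources
  do not — this asymmetry is also how a store loader distinguishes the two
  releases. The `category` coding is always LOINC 57016-8. The resource's
  own `status` is written `active` and, on read, mapped through the FHIR
  status table into provenance notes; it never overrides the policy code's
  label, because the interoperable status lives in the code.
* **IHE BPPC (CDA R2, XML).** One `documentationOf/serviceEvent` per
  record: `code`/`codeSystem` attributes hold the OIDs, `effectiveTime`
  `low`/`high` hold the period as `YYYYMMDD` (day precision fixed; finer
  precision is truncated with a logged warning), the patient is
  `recordTarget/patientRole/id`. Only the header is modelled; the
  structured body is an opaque placeholder. BPPC has no status attribute —
  the combined code is the sole status carrier, and a test asserts every
  label survives the BPPC round-trip for exactly this reason. Generated
  serviceEvent ids live under the documentation arc `2.999.2` so they can
  never collide with production identifiers. Emitted documents are checked
  by a structural header validator (namespace, the two BPPC templateIds,
  document code, serviceEvent shape).

A multi-policy FHIR resource has a single period, so the FHIR writer
requires all records of one document to share one period and raises
otherwise, telling the caller to split; the BPPC writer has no such
constraint (per-serviceEvent periods).

### Status mappings

The two published tables are implemented verbatim: of the six FHIR
lifecycle tokens only `active` maps to `valid`; of the four gICS states
(version 2.8.6) only `Accepted` maps to `valid`. Both maps are total on
their domains and deterministic; an out-of-domain token raises rather than
defaulting to `unknown`, which is reserved for absence of documentation.
The collapse onto three labels is deliberately lossy (several source
tokens share `not valid`), so readers keep the original token in record
provenance. The FHIR table applies identically to R3 and R4.

## The resolution engine

`effective_status(store, patient, policy, date)` filters the patient's
records for that policy by period containment and picks the winner by:

1. latest `recorded_at` (absent = earliest possible, so explicitly
   timestamped documentation outranks untimestamped);
2. latest period start (this alone makes withdrawal-as-new-record work,
   since a withdrawal necessarily starts after the consent it revokes);
3. deny-biased label order `not valid` ≺ `unknown` ≺ `valid` for exact
   ties.

No covering record resolves to `unknown` — including expired and
not-yet-started periods. Rationale: `not valid` is a *documented* state,
and both labels equally deny use downstream, so reading expiry as
`unknown` loses nothing while keeping "we have no applicable
documentation" distinct from "the patient said no". The function is total
and insertion-order independent; for a fixed (policy, date) the three
cohorts partition the store's patient universe. The engine is tested for
exact agreement with an independently written brute-force scan (flat
filter, sort by the documented tie-break, take first) on 10,000 randomized
queries.

### Validation

`validate_record` reports violations as data: a policy citing a module
absent from the template version, a missing start, and the five-year cap
on health-insurance-data modules (`kvdat_*` by default,
`insurance_cap_years = 5`). The latest admissible end for a start *s* is
*s* + 5 years − 1 day (so 2018-10-10 admits 2023-10-09), computed in
calendar years with Feb-29 starts clamped to Feb-28. The cap applies only
to records coding `valid`: a `not valid` record grants no permission, so a
withdrawal with an open-ended period is not a duration violation. An
open-ended `valid` period on a capped module *is* a violation — an
unbounded permission exceeds any maximum. Violations are never silently
truncated or repaired.

## Synthetic populations

The generator emulates a modular opt-in consent process: each patient
signs one consent document on an enrollment date drawn from a two-year
window starting 2018-01-01, answering Yes/No to each of the eight modules;
the document's validity is five years (end = start + 5 y − 1 day, the
worked example's shape, automatically within the insurance cap). Defaults
encode the reference scenario used throughout the tests: 100 patients, 30%
opt-in per module, one in six opted-in patients later withdrawing after a
uniform 30–720-day lag. Group sizes are exact by construction
(`round(p·n)` members, membership drawn from the seeded generator), so the
reference scenario yields exactly 30 opted-in and 5 withdrawn patients per
module — a deliberately reproducible cohort of 25. Draws use one
`random.Random(seed)` instance in a documented order (per-module group
membership first, then patients outer / modules inner), so a fixed seed
reproduces the population byte-for-byte on any platform.

Alongside the records the generator tabulates its own ground truth
directly from the generating events — at probe dates bracketing every
period boundary (±1 day), the mid-period date, and the withdrawal date
(±1 day) — which serves as the engine's primary acceptance oracle.

What the generator does *not* emulate: demographics (patients are opaque
identifiers under the `2.999.1` example arc), partial or per-module
signing dates within one document, conflicting simultaneous
documentation, or vocabulary drift in source systems. Passing tests on
synthetic populations therefore demonstrate the correctness of the
representation, conversion and resolution logic — not robustness to
malformed real-world exports beyond the error cases tested explicitly.

## Problem sizes and numerical choices

The test suite and the acceptance script use 1,000 record sets for the
conversion-chain check, 10,000 randomized queries for the engine-oracle
check, and 50–100-patient populations for cohort scenarios; these sizes
make every property check exhaustive enough to hit all label/period edge
cases while keeping a full run in the low seconds. There is no floating
point anywhere in the core: dates, OIDs and labels are discrete, so all
comparisons are exact.

## Known limitations

* Only the Consent fields of the worked representation are read/written;
  unknown incoming FHIR fields and CDA body content are not preserved
  through conversion (the three core data elements always are).
* No FHIR server interaction, no XDS transactions, no structured
  access-control policies (APPC/XACML) — the layer documents permissions,
  it does not enforce them.
* The bundled template is a synthetic stand-in: correct structure (four
  sections, eight opt-in modules, version string 1.6a), paraphrased
  statement texts.
* The registry persistence format is this package's own YAML schema, not
  the upstream registry's native export.
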