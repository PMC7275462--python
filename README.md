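# mii-consent

An interoperability layer for consent-based data-use permissions, built for
data integration centers that exchange patient consent information across
heterogeneous consent-management stacks (HL7 FHIR Consent resources in
Releases 3 and 4, IHE BPPC CDA R2 documents, gICS exports).

## The problem and the model

Sites documenting broad consent use different standards, and those standards
disagree about one crucial thing: whether a consent *status* can be carried
explicitly. FHIR has a resource-lifecycle `status` whose codes are still in
flux; BPPC has no status attribute at all. This package implements the
pragmatic resolution: a **policy-status code system** in which every code
identifies the combination of

* one *policy* — a consent module of a versioned template, or a regulatory
  data-use provision — with
* one of three *status labels*: `valid`, `not valid`, `unknown`.

Codes are OIDs allocated consecutively under a code system OID
(`2.16.840.1.113883.3.1937.777.24.5.1`), referenceable as bare OIDs (BPPC),
`urn:oid:` URNs (FHIR), or registry-lookup URIs. Because the status is baked
into the code, any profile that can carry a code can carry the status — this
is what makes the representation lossless across standards.

A documented statement (`ConsentRecord`) always carries three mandatory data
elements: the per-module status, the template version (inside the policy
reference), and the validity start date; an end date is optional. Withdrawal
is never a mutation: it is a *new* record coding `not valid` from the
withdrawal date. A temporal engine resolves the effective status of a patient
for a policy at a date (latest documentation wins; exact ties resolve
deny-biased: `not valid` ≺ `unknown` ≺ `valid`; no covering documentation
means `unknown`) and runs cohort queries on directories of mixed FHIR/BPPC
documents.

## Worked example

The bundled fixture is a FHIR R4 Consent resource for patient `patientf001`,
referencing policy-status code `2.16.840.1.113883.3.1937.777.24.5.1.1` with
validity 2018-10-10 through 2023-10-09. Resolving the code:

```bash
$ mii-consent registry lookup 2.16.840.1.113883.3.1937.777.24.5.1.1
{
  "code": "2.16.840.1.113883.3.1937.777.24.5.1.1",
  "codeSystem": "2.16.840.1.113883.3.1937.777.24.5.1",
  "policy": "mdat_collect_store_use",
  "template_version": "1.6a",
  "status": "valid",
  "display": "mdat_collect_store_use — valid"
}
```

i.e. the first module of template version 1.6a (use of clinical routine
data), status `valid` — the first of the 24 codes (8 modules × 3 labels)
the registry allocates for the bundled template. Converting the resource to
BPPC:

```bash
$ mii-consent convert --from fhir-r4 --to bppc tests/fixtures/fhir_r4_worked_example.json
<?xml version='1.0' encoding='UTF-8'?>
<ClinicalDocument xmlns="urn:hl7-org:v3">
  <templateId root="1.3.6.1.4.1.19376.1.5.3.1.1.1"/>
  <templateId root="1.3.6.1.4.1.19376.1.5.3.1.1.7"/>
  <code code="57016-8" displayName="PATIENT PRIVACY ACKNOWLEDGEMENT"
        codeSystem="2.16.840.1.113883.6.1" codeSystemName="LOINC"/>
  ...
  <documentationOf typeCode="DOC">
    <serviceEvent classCode="ACT" moodCode="EVN">
      <code code="2.16.840.1.113883.3.1937.777.24.5.1.1"
            codeSystem="2.16.840.1.113883.3.1937.777.24.5.1"/>
      <effectiveTime>
        <low value="20181010"/>
        <high value="20231009"/>
      </effectiveTime>
    </serviceEvent>
  </documentationOf>
  ...
```

The same code and the same period reappear in the CDA header's
`serviceEvent` — nothing is lost even though BPPC cannot express a status —
and the document code is LOINC 57016-8 ("patient privacy acknowledgement")
on both sides.

The library surface mirrors the CLI: `read_fhir_consent` / `write_fhir_consent`,
`read_bppc` / `write_bppc`, `convert`, `map_fhir_status` / `map_gics_status`,
`effective_status` / `cohort_query` / `validate_record`, and a seeded
synthetic-population generator (`generate_population`, `emit_documents`).

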