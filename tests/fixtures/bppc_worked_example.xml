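<?xml version="1.0" encoding="UTF-8"?>
<ClinicalDocument xmlns="urn:hl7-org:v3">
  <templateId root="1.3.6.1.4.1.19376.1.5.3.1.1.1"/>
  <templateId root="1.3.6.1.4.1.19376.1.5.3.1.1.7"/>
  <code code="57016-8" displayName="PATIENT PRIVACY ACKNOWLEDGEMENT"
        codeSystem="2.16.840.1.113883.6.1" codeSystemName="LOINC"/>
  <recordTarget>
    <patientRole>
      <id extension="0411886319605719371016" root="1.3.6.1.4.1.19376.1.8.9.2"/>
      <addr use="HP"/>
      <patient/>
    </patientRole>
  </recordTarget>
  <documentationOf typeCode="DOC">
    <serviceEvent classCode="ACT" moodCode="EVN">
      <templateId root="1.3.6.1.4.1.19376.1.5.3.1.2.6"/>
      <id root="1.2.3.4.5.6"/>
      <code code="2.16.840.1.113883.3.1937.777.24.5.1.1"
            codeSystem="2.16.840.1.113883.3.1937.777.24.5.1"/>
      <effectiveTime>
        <low value="20181010"/>
        <high value="20231009"/>
      </effectiveTime>
    </serviceEvent>
  </documentationOf>
  <component>
    <structuredBody/>
  </component>
</ClinicalDocument>
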