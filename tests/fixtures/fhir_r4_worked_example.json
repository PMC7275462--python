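{
  "resourceType": "Consent",
  "status": "active",
  "scope": {
    "coding": [
      {
        "system": "http://terminology.hl7.org/CodeSystem/consentscope",
        "code": "patient-privacy"
      }
    ]
  },
  "category": [
    {
      "coding": [
        {
          "system": "http://loinc.org",
          "code": "57016-8"
        }
      ]
    }
  ],
  "patient": {
    "identifier": {
      "value": "patientf001"
    }
  },
  "policy": [
    {
      "uri": "http://art-decor.org/decor/services/RetrieveCode?code=2.16.840.1.113883.3.1937.777.24.5.1.1&codeSystem=2.16.840.1.113883.3.1937.777.24.5.1"
    }
  ],
  "provision": {
    "period": {
      "start": "2018-10-10",
      "end": "2023-10-09"
    }
  }
}
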