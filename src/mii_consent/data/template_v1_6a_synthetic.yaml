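# Synthetic stand-in for the MII broad-consent template, version 1.6a.
# The real template's structure is reproduced — four sections (clinical
# routine data, health insurance data, biosamples, re-contact) holding a
# total of eight opt-in modules — but the statement texts are paraphrases,
# not the authoritative wording.
version: "1.6a"
sections:
  - "Use of clinical routine data"
  - "Use of health insurance data"
  - "Use of biosamples"
  - "Re-contact"
modules:
  - id: mdat_collect_store_use
    section: "Use of clinical routine data"
    statement: >
      I consent to the collection, processing, storage and scientific use
      of my clinical routine data as described in the patient information.
    choices: ["Yes", "No"]
  - id: mdat_share_analyze
    section: "Use of clinical routine data"
    statement: >
      I consent to the transfer of my clinical routine data to other
      research institutions for scientific analyses.
    choices: ["Yes", "No"]
  - id: kvdat_retrieve_5y
    section: "Use of health insurance data"
    statement: >
      I consent to the retrieval and scientific use of my health insurance
      data for a maximum of five years.
    choices: ["Yes", "No"]
  - id: kvdat_retro_5y
    section: "Use of health insurance data"
    statement: >
      I consent to the retrospective retrieval of my health insurance data
      covering up to five years before signing.
    choices: ["Yes", "No"]
  - id: biomat_collect_store_use
    section: "Use of biosamples"
    statement: >
      I consent to the storage and scientific use of leftover biosamples
      taken during my treatment.
    choices: ["Yes", "No"]
  - id: biomat_additional_quantities
    section: "Use of biosamples"
    statement: >
      I consent to the collection of small additional biosample quantities
      during routine procedures.
    choices: ["Yes", "No"]
  - id: recontact_further_projects
    section: "Re-contact"
    statement: >
      I consent to being contacted again to be informed about further
      research projects I could take part in.
    choices: ["Yes", "No"]
  - id: recontact_additional_data
    section: "Re-contact"
    statement: >
      I consent to being contacted again to be asked for additional
      information or data.
    choices: ["Yes", "No"]
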