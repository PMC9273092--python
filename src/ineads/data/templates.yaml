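# Telegraphic note-sentence templates used by the synthetic corpus generator.
# Each template carries exactly one {term} slot, filled with a lexicon term of
# the owning subcategory. Template wording is audited (and tested) to contain
# no lexicon term of any subcategory on its own, no negation trigger in the
# six tokens before the slot, and no backward trigger after it.
templates:
  married:
    - "surgical consent signed by {term} at bedside"
    - "{term} at bedside today updated on plan of care"
    - "phone call from {term} requesting update overnight"
    - "{term} will bring home meds list in am"
    - "per {term} pt baseline independent prior to admission"
  partnered:
    - "pt {term} phoned x 1 over noc"
    - "{term} at bedside providing support"
    - "spoke by phone with pt {term} re plan"
    - "{term} visited this evening brought clothing"
    - "contact info for {term} updated in chart"
  relatives_unknown_involvement:
    - "family history notable {term} in their 50s"
    - "pt has {term} in area involvement unclear"
    - "social history mentions {term} not recently in contact"
    - "{term} listed in chart as relative no role specified"
    - "per old notes pt has {term} out of state"
  caregiver_support:
    - "social work note {term} present at bedside"
    - "pt {term} assists with adls at home"
    - "{term} manages medications and appointments"
    - "home services coordinated by {term}"
    - "{term} identified on admission paperwork"
  living_with_others:
    - "social history pt {term} in two story home"
    - "{term} per intake assessment"
    - "pt {term} and has good support at home"
    - "housing stable pt {term} near downtown"
    - "per pt {term} who helps with shopping"
  community_connection:
    - "{term} bring meals several times weekly"
    - "pt active locally {term} per social work"
    - "many visitors today {term} noted by staff"
    - "pt describes {term} as main social outlet"
    - "{term} check in on pt regularly"
  religious_connections:
    - "{term} visited and prayed with pt"
    - "pt requests {term} be called in am"
    - "spiritual care consulted {term} to visit today"
    - "faith community important to pt {term} aware of admission"
    - "{term} provided support this afternoon"
  surrogate_identified:
    - "{term} regarding goals of care"
    - "{term} and plan confirmed with team"
    - "icu team notes {term} yesterday afternoon"
    - "{term} to pursue rehab placement"
    - "documentation reflects {term} this week"
  unmarried:
    - "social history pt {term} no children"
    - "pt {term} per social work intake"
    - "{term} for several years per pt"
    - "pt reports being {term} since 2008"
    - "admission form lists pt as {term}"
  living_alone:
    - "social history pt {term} in apartment"
    - "per ems pt found at home {term}"
    - "{term} independent with adls prior to admission"
    - "dispo planning pt {term} stairs to enter"
    - "42 yo pt {term} per triage note"
  transitionally_situated:
    - "social history etoh abuse {term} per ed notes"
    - "pt {term} for past several months"
    - "dispo complicated pt {term} at present"
    - "{term} prior to this admission per case management"
    - "pt {term} situation reviewed with social work"
  surrogate_unidentified:
    - "social dispo full code {term} per liver notes"
    - "attempts made overnight {term}"
    - "{term} despite multiple phone calls"
    - "team notes {term} at this time"
    - "{term} emergency contact line disconnected"
  palliative_care:
    - "{term} following team discussion"
    - "plan to involve {term} in am"
    - "{term} present at bedside discussion today"
    - "goals of care reviewed {term} on board"
    - "transitioned to {term} overnight"
  hospice:
    - "plan to discharge home with {term}"
    - "{term} evaluation requested by team"
    - "case management arranging {term}"
    - "family in agreement with {term}"
    - "pt accepted to {term} as of today"
  advance_directives_available:
    - "mother telephone fax 1 {term} yes"
    - "chart review {term} per admission paperwork"
    - "{term} copy scanned into record"
    - "confirmed with pt {term} unchanged"
    - "{term} recorded this admission"
  advance_directives_unavailable:
    - "{term} lack copy provided"
    - "chart review {term} at this time"
    - "{term} per pt and records"
    - "social work confirms {term}"
    - "{term} despite prior admissions"
  lacking_capacity:
    - "pt {term} unable to participate in discussion"
    - "neuro exam {term} throughout shift"
    - "pt remains {term} per overnight events"
    - "assessment {term} decision making limited"
    - "{term} documented by covering md"
distractors:
  - "vital signs stable afebrile overnight"
  - "lungs clear bilaterally on auscultation"
  - "tolerating po diet well"
  - "continue iv antibiotics per id recs"
  - "foley draining clear yellow urine"
  - "repeat labs in am per team"
  - "remains on room air sats 98"
  - "skin warm dry intact"
  - "ambulating in hallway with walker"
  - "wound dressing changed drainage minimal"
  - "pain controlled with tylenol prn"
  - "glucose monitored per sliding scale"
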