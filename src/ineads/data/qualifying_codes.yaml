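# Diagnosis-code prefixes marking admissions eligible for gold-standard
# sampling: psychiatric disorders, tuberculosis, hepatitis C, and HIV/AIDS.
# Patterns are regular expressions matched against the code with dots removed,
# case-insensitively. Both ICD-9-CM and ICD-10-CM forms are listed because
# source tables differ in coding era; the list is configuration, not a claim
# about any one dataset.
icd9:
  - "^29[0-9]"   # psychoses and other psychiatric disorders 290-299
  - "^30[0-9]"   # neurotic/personality/substance disorders 300-309
  - "^31[0-9]"   # other mental disorders 310-319
  - "^01[0-8]"   # tuberculosis 010-018
  - "^0704"      # hepatitis C acute
  - "^0705"      # hepatitis C chronic
  - "^042"       # HIV disease
icd10:
  - "^F"         # mental, behavioral and neurodevelopmental disorders
  - "^A1[5-9]"   # tuberculosis
  - "^B171"      # acute hepatitis C
  - "^B182"      # chronic hepatitis C
  - "^B2[0-4]"   # HIV disease
  - "^Z21"       # asymptomatic HIV status
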