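# Default outcome definitions: analyte, direction of abnormality, and
# nested mild/moderate/severe severity cutoffs in the canonical unit of
# each analyte.  These defaults follow widely used guideline families
# (e.g. whole-blood hypoglycemia grading, CTCAE-style cytopenia grades,
# KDIGO-style creatinine multiples) and are deliberately editable: the
# labeling engine reads every cutoff from this file, never from code.
#
# kind: absolute   -> cutoffs are values in the canonical unit
# kind: ref_high_multiple -> cutoffs are multiples of the admission's
#                            age-group/institution upper reference bound
#                            (used for hypercreatinemia / AKI)
canonical_units:
  creatinine: umol/L
  potassium: mmol/L
  glucose: mmol/L
  sodium: mmol/L
  anc: 10^9/L
  hemoglobin: g/L
  platelets: 10^9/L

outcomes:
  aki:
    analyte: creatinine
    direction: above
    kind: ref_high_multiple
    mild: 1.5
    moderate: 2.0
    severe: 3.0
    default_code: N17.9
  hyperkalemia:
    analyte: potassium
    direction: above
    kind: absolute
    mild: 5.5
    moderate: 6.0
    severe: 6.5
    default_code: E87.5
  hypoglycemia:
    analyte: glucose
    direction: below
    kind: absolute
    mild: 3.9
    moderate: 3.0
    severe: 2.2
    default_code: E16.2
  hyponatremia:
    analyte: sodium
    direction: below
    kind: absolute
    mild: 135.0
    moderate: 130.0
    severe: 125.0
    default_code: E87.1
  anemia:
    analyte: hemoglobin
    direction: below
    kind: absolute
    mild: 110.0
    moderate: 90.0
    severe: 70.0
    default_code: D64.9
  neutropenia:
    analyte: anc
    direction: below
    kind: absolute
    mild: 1.5
    moderate: 1.0
    severe: 0.5
    default_code: D70.9
  thrombocytopenia:
    analyte: platelets
    direction: below
    kind: absolute
    mild: 150.0
    moderate: 100.0
    severe: 50.0
    default_code: D69.6
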