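# Default diagnosis code sets, one per outcome.  Entries are
# (vocabulary, code-or-prefix, match mode).  These ICD-10 prefix sets are
# illustrative defaults for a coding audit; production use should replace
# them with locally validated code lists via the same file format.
aki:
  - {vocabulary: ICD10, code: N17, mode: prefix}
hyperkalemia:
  - {vocabulary: ICD10, code: E87.5, mode: prefix}
hypoglycemia:
  - {vocabulary: ICD10, code: E16.0, mode: prefix}
  - {vocabulary: ICD10, code: E16.1, mode: prefix}
  - {vocabulary: ICD10, code: E16.2, mode: prefix}
hyponatremia:
  - {vocabulary: ICD10, code: E87.1, mode: prefix}
anemia:
  - {vocabulary: ICD10, code: D50, mode: prefix}
  - {vocabulary: ICD10, code: D51, mode: prefix}
  - {vocabulary: ICD10, code: D52, mode: prefix}
  - {vocabulary: ICD10, code: D53, mode: prefix}
  - {vocabulary: ICD10, code: D55, mode: prefix}
  - {vocabulary: ICD10, code: D56, mode: prefix}
  - {vocabulary: ICD10, code: D57, mode: prefix}
  - {vocabulary: ICD10, code: D58, mode: prefix}
  - {vocabulary: ICD10, code: D59, mode: prefix}
  - {vocabulary: ICD10, code: D60, mode: prefix}
  - {vocabulary: ICD10, code: D61, mode: prefix}
  - {vocabulary: ICD10, code: D62, mode: prefix}
  - {vocabulary: ICD10, code: D63, mode: prefix}
  - {vocabulary: ICD10, code: D64, mode: prefix}
neutropenia:
  - {vocabulary: ICD10, code: D70, mode: prefix}
thrombocytopenia:
  - {vocabulary: ICD10, code: D69.6, mode: prefix}
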