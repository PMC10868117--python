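# Named simulation presets (study conditions for the synthetic cohorts).
# Severity prevalence vectors are (none, mild band, moderate band, severe
# band) and are shared across presets; what varies is coding behaviour.
_shared:
  testing: &testing
    creatinine: 0.5
    potassium: 0.5
    glucose: 0.6
    sodium: 0.5
    anc: 0.4
    hemoglobin: 0.6
    platelets: 0.6
  prev:
    aki: &prev_aki [0.90, 0.05, 0.03, 0.02]
    hyperkalemia: &prev_hyperkalemia [0.93, 0.04, 0.02, 0.01]
    hypoglycemia: &prev_hypoglycemia [0.93, 0.04, 0.02, 0.01]
    hyponatremia: &prev_hyponatremia [0.88, 0.07, 0.03, 0.02]
    anemia: &prev_anemia [0.70, 0.12, 0.12, 0.06]
    neutropenia: &prev_neutropenia [0.92, 0.03, 0.03, 0.02]
    thrombocytopenia: &prev_thrombocytopenia [0.85, 0.07, 0.05, 0.03]
  coding:
    balanced: &coding_balanced
      aki: {prevalence: *prev_aki, coding_sensitivity: [0.25, 0.35, 0.45], false_positive_rate: 0.01}
      hyperkalemia: {prevalence: *prev_hyperkalemia, coding_sensitivity: [0.25, 0.35, 0.45], false_positive_rate: 0.01}
      hypoglycemia: {prevalence: *prev_hypoglycemia, coding_sensitivity: [0.25, 0.35, 0.45], false_positive_rate: 0.01}
      hyponatremia: {prevalence: *prev_hyponatremia, coding_sensitivity: [0.25, 0.35, 0.45], false_positive_rate: 0.01}
      anemia: {prevalence: *prev_anemia, coding_sensitivity: [0.25, 0.35, 0.45], false_positive_rate: 0.01}
      neutropenia: {prevalence: *prev_neutropenia, coding_sensitivity: [0.25, 0.35, 0.45], false_positive_rate: 0.01}
      thrombocytopenia: {prevalence: *prev_thrombocytopenia, coding_sensitivity: [0.25, 0.35, 0.45], false_positive_rate: 0.01}
    sparse: &coding_sparse
      aki: {prevalence: *prev_aki, coding_sensitivity: [0.05, 0.08, 0.12], false_positive_rate: 0.003}
      hyperkalemia: {prevalence: *prev_hyperkalemia, coding_sensitivity: [0.05, 0.08, 0.12], false_positive_rate: 0.003}
      hypoglycemia: {prevalence: *prev_hypoglycemia, coding_sensitivity: [0.05, 0.08, 0.12], false_positive_rate: 0.003}
      hyponatremia: {prevalence: *prev_hyponatremia, coding_sensitivity: [0.05, 0.08, 0.12], false_positive_rate: 0.003}
      anemia: {prevalence: *prev_anemia, coding_sensitivity: [0.05, 0.08, 0.12], false_positive_rate: 0.003}
      neutropenia: {prevalence: *prev_neutropenia, coding_sensitivity: [0.05, 0.08, 0.12], false_positive_rate: 0.003}
      thrombocytopenia: {prevalence: *prev_thrombocytopenia, coding_sensitivity: [0.05, 0.08, 0.12], false_positive_rate: 0.003}
    rich: &coding_rich
      aki: {prevalence: *prev_aki, coding_sensitivity: [0.35, 0.45, 0.55], false_positive_rate: 0.02}
      hyperkalemia: {prevalence: *prev_hyperkalemia, coding_sensitivity: [0.35, 0.45, 0.55], false_positive_rate: 0.02}
      hypoglycemia: {prevalence: *prev_hypoglycemia, coding_sensitivity: [0.35, 0.45, 0.55], false_positive_rate: 0.02}
      hyponatremia: {prevalence: *prev_hyponatremia, coding_sensitivity: [0.35, 0.45, 0.55], false_positive_rate: 0.02}
      anemia: {prevalence: *prev_anemia, coding_sensitivity: [0.35, 0.45, 0.55], false_positive_rate: 0.02}
      neutropenia: {prevalence: *prev_neutropenia, coding_sensitivity: [0.35, 0.45, 0.55], false_positive_rate: 0.02}
      thrombocytopenia: {prevalence: *prev_thrombocytopenia, coding_sensitivity: [0.35, 0.45, 0.55], false_positive_rate: 0.02}
    moderate: &coding_moderate
      aki: {prevalence: *prev_aki, coding_sensitivity: [0.2, 0.3, 0.4], false_positive_rate: 0.01}
      hyperkalemia: {prevalence: *prev_hyperkalemia, coding_sensitivity: [0.2, 0.3, 0.4], false_positive_rate: 0.01}
      hypoglycemia: {prevalence: *prev_hypoglycemia, coding_sensitivity: [0.2, 0.3, 0.4], false_positive_rate: 0.01}
      hyponatremia: {prevalence: *prev_hyponatremia, coding_sensitivity: [0.2, 0.3, 0.4], false_positive_rate: 0.01}
      anemia: {prevalence: *prev_anemia, coding_sensitivity: [0.2, 0.3, 0.4], false_positive_rate: 0.01}
      neutropenia: {prevalence: *prev_neutropenia, coding_sensitivity: [0.2, 0.3, 0.4], false_positive_rate: 0.01}
      thrombocytopenia: {prevalence: *prev_thrombocytopenia, coding_sensitivity: [0.2, 0.3, 0.4], false_positive_rate: 0.01}

"null":
  intercept_sd: 1.0
  seed: 0
  institutions:
    - name: site_a
      n_patients: 1500
      testing_prob_per_day: *testing
      outcomes: *coding_balanced
    - name: site_b
      n_patients: 1500
      testing_prob_per_day: *testing
      outcomes: *coding_balanced

similar-labs-different-coding:
  intercept_sd: 1.0
  seed: 0
  institutions:
    - name: site_a
      n_patients: 1500
      testing_prob_per_day: *testing
      outcomes: *coding_sparse
    - name: site_b
      n_patients: 1500
      testing_prob_per_day: *testing
      outcomes: *coding_rich

unit-heterogeneous-coding:
  intercept_sd: 1.0
  seed: 0
  institutions:
    - name: site_a
      n_patients: 1500
      testing_prob_per_day: *testing
      outcomes: *coding_moderate
      n_units: 24
      unit_acuity_sd: 0.6
      unit_coding_shift_sd: 2.0
    - name: site_b
      n_patients: 1500
      testing_prob_per_day: *testing
      outcomes: *coding_moderate
      n_units: 24
      unit_acuity_sd: 0.6
      unit_coding_shift_sd: 0.0
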