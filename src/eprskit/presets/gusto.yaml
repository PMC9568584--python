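# 7-component postnatal adversity score (GUSTO-style cut-offs).
# Relative to the 10-component preset, components without source data in
# this cohort design (lack of money, domestic violence, pregnancy anxiety)
# are absent, and questionnaire cut-offs differ where noted.
components:
  - name: hospitalization
    rules:
      - {column: hospitalization_6m, comparison: is_true}
  - name: birth_size_percentile
    rules:
      - {column: birth_percentile, comparison: less, threshold: 10}
      - {column: birth_percentile, comparison: greater, threshold: 90}
  - name: gestational_age
    rules:
      - {column: gestational_age_weeks, comparison: less_equal, threshold: 37}
  - name: maternal_mental_health
    rules:
      - {column: bdi, comparison: greater, threshold: 13}
      - {column: epds, comparison: greater_equal, threshold: 12}
      - {column: stai, comparison: greater, threshold: 92}
  - name: low_income
    rules:
      - {column: household_income_monthly, comparison: less, threshold: 2000}
  - name: poor_family_function
    rules:
      - {column: fad_score, comparison: greater_equal, threshold: 2.17}
  - name: smoking_pregnancy
    rules:
      - {column: smoked_pregnancy, comparison: is_true}
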