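# 10-component postnatal adversity score (MAVAN-style cut-offs).
# Each component contributes one point when any of its rules fires.
# Thresholds are editable; comparisons follow the printed cut-off wording
# (e.g. "below or equal to 37 weeks" -> less_equal; "below 30,000$" -> less).
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
      - {column: bdi, comparison: greater, threshold: 14}
      - {column: epds, comparison: greater, threshold: 9}
      - {column: stai, comparison: greater, threshold: 92}
  - name: low_income
    rules:
      - {column: household_income, comparison: less, threshold: 30000}
  - name: lack_of_money
    rules:
      - {column: lack_of_money, comparison: greater, threshold: 7}
  - name: poor_family_function
    rules:
      - {column: fad_score, comparison: greater_equal, threshold: 2.00}
  - name: domestic_violence_or_abuse
    rules:
      - {column: domestic_violence, comparison: is_true}
  - name: smoking_pregnancy
    rules:
      - {column: smoked_pregnancy, comparison: is_true}
  - name: pregnancy_anxiety
    rules:
      - {column: pregnancy_anxiety, comparison: greater, threshold: 1.95}
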