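# Default synthetic cohort: 233 patients followed 540 days (18 months),
# mixing three engagement archetypes.  Self-logging menus (meal, exercise,
# weight, step count) are used habitually by engaged patients; messaging and
# content reading are occasional for everyone, so they mostly add noise to
# menu-level summaries.  Dropout hazard is loyalty-dominated: patients who
# visit regularly keep using the app far longer than sporadic ones.
n_patients: 233
study_length_days: 540
base_weekly_hazard: 0.15
archetypes:
  - label: engaged_regular
    proportion: 0.30
    weekly_visit_prob: 0.90
    visits_per_active_week: 4.0
    decay_rate: 0.998
    menu_probs:
      meal_log: 0.80
      exercise_log: 0.60
      message_sent: 0.15
      reading_content: 0.15
      weight_log: 0.50
      step_count: 0.90
    dropout_log_hazard_coeffs: {mi: -0.3, li: -2.5, ri: -0.3}
  - label: engaged_decaying
    proportion: 0.40
    weekly_visit_prob: 0.85
    visits_per_active_week: 3.0
    decay_rate: 0.97
    menu_probs:
      meal_log: 0.70
      exercise_log: 0.50
      message_sent: 0.15
      reading_content: 0.15
      weight_log: 0.40
      step_count: 0.80
    dropout_log_hazard_coeffs: {mi: -0.3, li: -2.5, ri: -0.3}
  - label: sporadic
    proportion: 0.30
    weekly_visit_prob: 0.35
    visits_per_active_week: 1.5
    decay_rate: 0.96
    menu_probs:
      meal_log: 0.50
      exercise_log: 0.30
      message_sent: 0.20
      reading_content: 0.20
      weight_log: 0.30
      step_count: 0.60
    dropout_log_hazard_coeffs: {mi: -0.3, li: -2.5, ri: -0.3}
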