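# Hypothetical 30-day-recall retrospective survey, Lugufu and Mtabila
# camps (Tanzania).  Systematic sampling, 3201 households, 40 interviewers.
site_id: tanzania
recall_label: 30d
n_households: 3201
n_clusters: 0
n_interviewers: 40
team_size: 1
n_key_informants: 35
activities:
  preparation:
    - {rule: observed_copy}
  training:
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 4}
    - {rule: fixed_team_days, role: data_collector, n_staff: 40, days: 4}
  data_collection:
    - {rule: per_household, role: data_collector, minutes_per_household: 15}
    - {rule: per_new_household_selection, role: data_collector, minutes: 3}
    - {rule: per_informant, n_informants: 35, minutes_each: 30}
    - {rule: respondent_time, minutes_per_household: 15}
    - {rule: proportional, role: investigator, source: data_collector, divisor: 40}
    - {rule: proportional, role: driver, source: investigator, factor: 1}
  data_entry_analysis:
    - {rule: per_questionnaire_entry, role: investigator, minutes_per_questionnaire: 3, double_entry_fraction: 0.2}
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 2}
  report:
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 2}
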