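# Hypothetical 6-month-recall retrospective survey, Mae La camp.
# Linear systematic sampling from household lists (no clusters):
# 480 households, 6 interviewers, 22 section chiefs as key informants.
site_id: mae_la
recall_label: 6mo
n_households: 480
n_clusters: 0
n_interviewers: 6
team_size: 1
n_key_informants: 22
activities:
  preparation:
    - {rule: observed_copy}
  training:
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 4}
    - {rule: fixed_team_days, role: data_collector, n_staff: 6, days: 4}
  data_collection:
    - {rule: per_household, role: data_collector, minutes_per_household: 15}
    - {rule: per_new_household_selection, role: data_collector, minutes: 3}
    - {rule: per_informant, n_informants: 22, minutes_each: 30}
    - {rule: respondent_time, minutes_per_household: 15}
    - {rule: proportional, role: investigator, source: data_collector, divisor: 6}
  data_entry_analysis:
    - {rule: per_questionnaire_entry, role: investigator, minutes_per_questionnaire: 3, double_entry_fraction: 0.2}
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 2}
  report:
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 2}
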