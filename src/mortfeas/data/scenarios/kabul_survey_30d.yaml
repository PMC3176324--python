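# Hypothetical 30-day-recall retrospective survey, District 1 of Kabul.
# 200 clusters x 32 households as stated in the source design (6402
# households; the stated household total is kept verbatim).
site_id: kabul
recall_label: 30d
n_households: 6402
n_clusters: 200
n_interviewers: 80
team_size: 2
n_key_informants: 200
activities:
  preparation:
    - {rule: observed_copy}
  training:
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 4}
    - {rule: fixed_team_days, role: data_collector, n_staff: 80, days: 4}
  data_collection:
    - {rule: per_cluster, role: data_collector, hours_per_cluster: 1, applies: preparation}
    - {rule: per_household, role: data_collector, minutes_per_household: 15, staff_per_household: 2}
    - {rule: per_new_household_selection, role: data_collector, minutes: 3}
    - {rule: per_informant, n_informants: 200, minutes_each: 30}
    - {rule: respondent_time, minutes_per_household: 15}
    - {rule: proportional, role: investigator, source: data_collector, divisor: 80}
    - {rule: proportional, role: driver, source: investigator, factor: 2}
  data_entry_analysis:
    - {rule: per_questionnaire_entry, role: investigator, minutes_per_questionnaire: 3, double_entry_fraction: 0.2}
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 2}
  report:
    - {rule: fixed_team_days, role: investigator, n_staff: 1, days: 2}
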