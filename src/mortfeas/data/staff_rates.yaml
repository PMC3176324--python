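# Hourly staff costs (US$/h) and exchange rates by site, as used to price
# field exercises.  Respondents, FGD participants and key informants are
# not paid and are priced at $0 automatically.  The Chiradzulu "other
# staff" entry is a one-off lump sum to household enumerators for the
# population count, not an hourly wage.
sites:
  kabul:
    currency: {code: AFN, units_per_usd: 50.20, as_of: "2008-07-14"}
    rates:
      investigator: {hourly_usd: 22.6}
      other_staff: {hourly_usd: 5.3}
      collaborator: {hourly_usd: 5.4}
      data_collector: {hourly_usd: 3.9}
      driver: {hourly_usd: 4.7}
  mae_la:
    currency: {code: THB, units_per_usd: 33.87, as_of: "2008-07-11"}
    rates:
      investigator: {hourly_usd: 22.6}
      other_staff: {hourly_usd: 4.5}
      collaborator: {hourly_usd: 9.9}
      data_collector: {hourly_usd: 4.5}
  chiradzulu:
    currency: {code: MWK, units_per_usd: 143.29, as_of: "2008-08-26"}
    rates:
      investigator: {hourly_usd: 22.6}
      other_staff: {hourly_usd: 0.0, lump_sum_usd: 264.0, lump_activity: population_estimation}
      collaborator: {hourly_usd: 5.7}
      data_collector: {hourly_usd: 2.3}
      driver: {hourly_usd: 27.0}
  tanzania:
    currency: {code: TZS, units_per_usd: 1186.53, as_of: "2008-10-03"}
    rates:
      investigator: {hourly_usd: 22.6}
      other_staff: {hourly_usd: 3.3}
      collaborator: {hourly_usd: 3.5}
      data_collector: {hourly_usd: 3.1}
      driver: {hourly_usd: 2.2}
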