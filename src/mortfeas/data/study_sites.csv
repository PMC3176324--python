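site_id,population_total,population_under5,recall_days,n_sectors,label,deaths,deaths_under5,sensitivity_60d,sensitivity_30d
kabul,76476,13790,60,24,"District 1, Kabul",67,20,62.6,55.0
mae_la,43794,5384,60,22,"Mae La camp",27,2,45.0,64.0
chiradzulu,54418,9462,60,96,"Chiradzulu District",93,26,65.0,72.5
tanzania,80136,16028,60,23,"Lugufu and Mtabila camps, Tanzania",44,22,53.0,67.7
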