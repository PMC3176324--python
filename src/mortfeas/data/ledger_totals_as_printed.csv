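site_id,method,hours,usd
kabul,informant,1481,11933
kabul,survey_6mo,2138,13060
kabul,survey_30d,12628,63223
mae_la,informant,168,1065
mae_la,survey_6mo,600,4395
mae_la,survey_30d,3547,19729
chiradzulu,informant,2069,15158
chiradzulu,survey_6mo,1734,15804
chiradzulu,survey_30d,10098,80818
tanzania,informant,444,2572
tanzania,survey_6mo,674,4401
tanzania,survey_30d,3695,17368
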