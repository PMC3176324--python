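site_id,method,role,hours,usd
kabul,informant,investigator,336,7582
kabul,informant,other_staff,104,546
kabul,informant,data_collector,721,2774
kabul,informant,driver,184,864
kabul,informant,collaborator,31,167
kabul,informant,respondent,24,0
kabul,informant,fgd_participant,24,0
kabul,informant,key_informant,58,0
kabul,survey_6mo,investigator,298,6735
kabul,survey_6mo,other_staff,0,0
kabul,survey_6mo,data_collector,1345,5178
kabul,survey_6mo,driver,215,1012
kabul,survey_6mo,collaborator,25,135
kabul,survey_6mo,respondent,240,0
kabul,survey_6mo,fgd_participant,0,0
kabul,survey_6mo,key_informant,15,0
kabul,survey_30d,investigator,1058,23921
kabul,survey_30d,other_staff,0,0
kabul,survey_30d,data_collector,8829,33993
kabul,survey_30d,driver,1100,5174
kabul,survey_30d,collaborator,25,135
kabul,survey_30d,respondent,1601,0
kabul,survey_30d,fgd_participant,0,0
kabul,survey_30d,key_informant,15,0
mae_la,informant,investigator,38,859
mae_la,informant,other_staff,14,63
mae_la,informant,data_collector,23,104
mae_la,informant,driver,0,0
mae_la,informant,collaborator,4,40
mae_la,informant,respondent,8,0
mae_la,informant,fgd_participant,67,0
mae_la,informant,key_informant,14,0
mae_la,survey_6mo,investigator,125,2825
mae_la,survey_6mo,other_staff,0,0
mae_la,survey_6mo,data_collector,340,1530
mae_la,survey_6mo,driver,0,0
mae_la,survey_6mo,collaborator,4,40
mae_la,survey_6mo,respondent,120,0
mae_la,survey_6mo,fgd_participant,0,0
mae_la,survey_6mo,key_informant,11,0
mae_la,survey_30d,investigator,424,9586
mae_la,survey_30d,other_staff,0,0
mae_la,survey_30d,data_collector,2245,10103
mae_la,survey_30d,driver,0,0
mae_la,survey_30d,collaborator,4,40
mae_la,survey_30d,respondent,800,0
mae_la,survey_30d,fgd_participant,0,0
mae_la,survey_30d,key_informant,73,0
chiradzulu,informant,investigator,258,5831
chiradzulu,informant,other_staff,849,264
chiradzulu,informant,data_collector,494,1136
chiradzulu,informant,driver,288,7767
chiradzulu,informant,collaborator,28,160
chiradzulu,informant,respondent,25,0
chiradzulu,informant,fgd_participant,33,0
chiradzulu,informant,key_informant,94,0
chiradzulu,survey_6mo,investigator,283,6396
chiradzulu,survey_6mo,other_staff,0,0
chiradzulu,survey_6mo,data_collector,902,2075
chiradzulu,survey_6mo,driver,266,7174
chiradzulu,survey_6mo,collaborator,28,160
chiradzulu,survey_6mo,respondent,240,0
chiradzulu,survey_6mo,fgd_participant,0,0
chiradzulu,survey_6mo,key_informant,15,0
chiradzulu,survey_30d,investigator,1214,27426
chiradzulu,survey_30d,other_staff,0,0
chiradzulu,survey_30d,data_collector,5665,13029
chiradzulu,survey_30d,driver,1491,40203
chiradzulu,survey_30d,collaborator,28,160
chiradzulu,survey_30d,respondent,1601,0
chiradzulu,survey_30d,fgd_participant,0,0
chiradzulu,survey_30d,key_informant,100,0
tanzania,informant,investigator,85,1921
tanzania,informant,other_staff,18,59
tanzania,informant,data_collector,131,406
tanzania,informant,driver,30,66
tanzania,informant,collaborator,34,119
tanzania,informant,respondent,16,0
tanzania,informant,fgd_participant,83,0
tanzania,informant,key_informant,47,0
tanzania,survey_6mo,investigator,141,3187
tanzania,survey_6mo,other_staff,0,0
tanzania,survey_6mo,data_collector,342,1060
tanzania,survey_6mo,driver,24,53
tanzania,survey_6mo,collaborator,29,102
tanzania,survey_6mo,respondent,120,0
tanzania,survey_6mo,fgd_participant,0,0
tanzania,survey_6mo,key_informant,18,0
tanzania,survey_30d,investigator,440,9948
tanzania,survey_30d,other_staff,0,0
tanzania,survey_30d,data_collector,2247,6966
tanzania,survey_30d,driver,160,352
tanzania,survey_30d,collaborator,29,102
tanzania,survey_30d,respondent,800,0
tanzania,survey_30d,fgd_participant,0,0
tanzania,survey_30d,key_informant,18,0
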