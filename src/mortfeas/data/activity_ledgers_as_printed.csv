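site_id,method,activity,hours,usd
kabul,informant,preparation,199,2543
kabul,informant,population_estimation,107,1076
kabul,informant,fgd,179,1279
kabul,informant,training,171,1165
kabul,informant,data_collection,810,5513
kabul,informant,data_entry_analysis,8,181
kabul,informant,report,8,181
kabul,survey_6mo,preparation,199,2543
kabul,survey_6mo,population_estimation,0,0
kabul,survey_6mo,fgd,0,0
kabul,survey_6mo,training,416,2202
kabul,survey_6mo,data_collection,1425,6101
kabul,survey_6mo,data_entry_analysis,82,1853
kabul,survey_6mo,report,16,362
kabul,survey_30d,preparation,199,2543
kabul,survey_30d,population_estimation,0,0
kabul,survey_30d,fgd,0,0
kabul,survey_30d,training,2593,10584
kabul,survey_30d,data_collection,9420,40690
kabul,survey_30d,data_entry_analysis,400,9044
kabul,survey_30d,report,16,362
mae_la,informant,preparation,16,238
mae_la,informant,population_estimation,0,0
mae_la,informant,fgd,88,257
mae_la,informant,training,6,63
mae_la,informant,data_collection,53,393
mae_la,informant,data_entry_analysis,1,23
mae_la,informant,report,4,90
mae_la,survey_6mo,preparation,16,238
mae_la,survey_6mo,population_estimation,0,0
mae_la,survey_6mo,fgd,0,0
mae_la,survey_6mo,training,224,1587
mae_la,survey_6mo,data_collection,299,1190
mae_la,survey_6mo,data_entry_analysis,45,1017
mae_la,survey_6mo,report,16,362
mae_la,survey_30d,preparation,16,238
mae_la,survey_30d,population_estimation,0,0
mae_la,survey_30d,fgd,0,0
mae_la,survey_30d,training,1313,6486
mae_la,survey_30d,data_collection,1994,7940
mae_la,survey_30d,data_entry_analysis,208,4703
mae_la,survey_30d,report,16,362
chiradzulu,informant,preparation,185,2668
chiradzulu,informant,population_estimation,1003,2595
chiradzulu,informant,fgd,67,364
chiradzulu,informant,training,160,957
chiradzulu,informant,data_collection,625,7919
chiradzulu,informant,data_entry_analysis,21,475
chiradzulu,informant,report,8,181
chiradzulu,survey_6mo,preparation,185,2668
chiradzulu,survey_6mo,population_estimation,0,0
chiradzulu,survey_6mo,fgd,0,0
chiradzulu,survey_6mo,training,224,1165
chiradzulu,survey_6mo,data_collection,1227,9756
chiradzulu,survey_6mo,data_entry_analysis,82,1853
chiradzulu,survey_6mo,report,16,362
chiradzulu,survey_30d,preparation,185,2668
chiradzulu,survey_30d,population_estimation,0,0
chiradzulu,survey_30d,fgd,0,0
chiradzulu,survey_30d,training,1313,3669
chiradzulu,survey_30d,data_collection,8184,65076
chiradzulu,survey_30d,data_entry_analysis,400,9044
chiradzulu,survey_30d,report,16,362
tanzania,informant,preparation,59,663
tanzania,informant,population_estimation,0,0
tanzania,informant,fgd,118,210
tanzania,informant,training,71,571
tanzania,informant,data_collection,177,699
tanzania,informant,data_entry_analysis,9,203
tanzania,informant,report,10,226
tanzania,survey_6mo,preparation,59,663
tanzania,survey_6mo,population_estimation,0,0
tanzania,survey_6mo,fgd,0,0
tanzania,survey_6mo,training,224,1318
tanzania,survey_6mo,data_collection,330,1042
tanzania,survey_6mo,data_entry_analysis,45,1017
tanzania,survey_6mo,report,16,362
tanzania,survey_30d,preparation,59,663
tanzania,survey_30d,population_estimation,0,0
tanzania,survey_30d,fgd,0,0
tanzania,survey_30d,training,1313,4693
tanzania,survey_30d,data_collection,2099,6947
tanzania,survey_30d,data_entry_analysis,208,4703
tanzania,survey_30d,report,16,362
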