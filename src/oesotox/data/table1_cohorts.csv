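study_id,n,events,cdmax_rep_gy_eqd2,chemo_fraction,interval_rep_months,followup_rep_months,cdmax_min,cdmax_max,interval_min,interval_max,toxicity_pct_printed,tumour_type,events_source,dual_timing_patients
poltinnikov,9,0,82.2,0.333,13,5.5,66.8,96.3,2,39,0,nsclc,rate_rounded,0
yamaguchi,12,6,93.8,1.0,8.5,4,87.0,98.9,4,162,50,oesophagus,event_table,1
kim,10,3,98.7,0.30,15.6,4.9,93.8,111.5,4.8,36.4,30,oesophagus,event_table,0
katano,4,1,88.2,0.833,17.4,8.8,71.9,97.9,6.4,59.2,16.7,oesophagus,event_table,0
hong_oes,39,3,112,0.50,16,87,80,140,3,168,7.7,oesophagus,event_table,0
zhou,55,11,115.2,NR,12,20,NR,NR,6,56,20,oesophagus,event_table,0
chen,36,19,99.2,1.0,14.6,62,99.2,107.7,4.5,165,52.8,oesophagus,event_table,7
kennedy,21,0,18.7,0.0,23,24,4.9,37.2,7,52,0,nsclc,rate_rounded,0
schlampp,62,2,89.9,0.032,14,8.2,NR,NR,3,103,4.8,nsclc,event_table,0
schroder,30,0,81.0,0.0,14,13,70.2,103.8,2,184,0,nsclc,rate_rounded,0
meijneke,8,0,85.2,0.0,17,12,70.5,123.2,2,33,0,nsclc,rate_rounded,0
owen,18,0,62.5,0.0,18.4,21.2,38.9,78.4,1.5,112.8,0,nsclc,rate_rounded,0
kilburn,33,1,69,0.0,18,17,11,129,6,61,3,nsclc,event_table,0
sumita,21,0,73,0.05,26.8,22.1,NR,NR,11.4,92.3,0,nsclc,rate_rounded,0
binkley,38,1,44.1,0.237,16,17,3.7,220.6,1,71,2.6,nsclc,event_table,0
maranzano,18,0,45,0.0,18,57,4,138,6,90,0,nsclc_or_mets,rate_rounded,0
ho,27,0,84.8,0.48,29.5,11.2,57.1,121,0.1,212.3,0,nsclc,rate_rounded,0
hong_nsclc,31,0,74.4,0.097,15.1,17.4,NR,NR,4.4,56.3,0,nsclc,rate_rounded,0
ogawa,31,0,19.4,0.0,NR,26,0.8,146.8,NR,NR,0,nsclc_or_mets,rate_rounded,0
griffioen,1,1,120,NR,62,6,NR,NR,NR,NR,100,nsclc,event_table,0
mcavoy,1,1,135.7,NR,36,29,NR,NR,NR,NR,100,nsclc,event_table,0
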