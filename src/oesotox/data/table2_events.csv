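study_id,timing,grade,category,count
yamaguchi,acute,3,perforation_tof,2
yamaguchi,acute,3,oesophagitis_dysphagia,1
yamaguchi,acute,4,perforation_tof,1
yamaguchi,late,3,stenosis,1
yamaguchi,late,3,perforation_tof,1
yamaguchi,late,5,bleeding,1
kim,acute,5,perforation_tof,3
mcavoy,late,4,perforation_tof,1
griffioen,late,3,oesophagitis_dysphagia,1
kilburn,late,5,bleeding,1
binkley,late,3,oesophagitis_dysphagia,1
katano,late,3,oesophagitis_dysphagia,1
hong_oes,late,3,perforation_tof,3
zhou,late,5,perforation_tof,11
chen,acute,3,oesophagitis_dysphagia,19
chen,late,4,perforation_tof,7
schlampp,late,3,stenosis,1
schlampp,late,4,perforation_tof,1
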