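site_id,plot_id,subplot_id,species,dbh_cm,height_m
S01,S01P1,1,sp001,10.0,8.2
S01,S01P1,2,sp002,5.5,n/a
S01,S01P1,3,sp001,12.3,9.1
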