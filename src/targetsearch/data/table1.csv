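protein,function,mass_kda,copies_per_cell,dstar_mobile,d_free,d_free_predicted,pct_long_lived,pct_transient,pct_free,footprint_bp
MukB,chromosome organization,1006,100,0.44,1.2,False,58,24,18,10
RNAP,transcription,478,4000,0.36,2.7,False,45,48,7,70
Gyrase,supercoiling,424,600,0.35,2.4,True,55,38,7,100
TopoIV,supercoiling/decatenation,366,80,0.40,2.7,True,37,52,11,10
UvrA,DNA repair,270,80,0.36,3.4,True,43,51,6,10
MutS,DNA repair,248,100,0.37,3.7,True,26,68,6,10
LacI,gene regulation,220,40,0.40,3.3,False,41,55,4,10
Pol1,DNA repair/replication,128,500,1.04,6.6,False,4,58,37,10
LigA,DNA repair/replication,102,100,1.18,6.9,False,7,56,37,10
H-NS,nucleoid-associated protein,87,20000,0.41,8.0,True,73,27,0.1,30
HU,nucleoid-associated protein,48,30000,0.33,12.6,True,23,77,0.4,36
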