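kind,bt_s,t_c,v_ms,dt_min,sec_mj_kg,vc_mg_100g,rc
prediction,93,89,1.2,366.7,1.43,4.19,3.35
validation,93,89,1.2,372,1.46,4.08,3.25
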