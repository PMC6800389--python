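survey_id,cluster_id,country_id,x,y,polygon_id
S01,S01_c01,C00,5.0,5.0,
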