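survey_id,cluster_id,birth_date,interview_date,outcome,age_at_death_months
S01,S01_c01,2003.0,2005.5,died,0.5
S01,S01_c01,2004.5,2005.0,alive_at_interview,
S01,S01_c01,2001.25,2005.5,died,14.0
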