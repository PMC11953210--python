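study_id,region,sex_group,site,mean_t,n,note
eu_fn_study_a_synthetic,EU,F,FN,-3.05,,synthetic illustrative study mean
eu_fn_study_b_synthetic,EU,F,FN,-2.77,,synthetic illustrative study mean
eu_fn_study_a_synthetic,EU,M,FN,-2.50,,synthetic illustrative study mean
eu_fn_study_b_synthetic,EU,M,FN,-2.14,,synthetic illustrative study mean
eu_fn_study_c_synthetic,EU,mixed,FN,-2.70,,synthetic illustrative study mean
eu_fn_study_d_synthetic,EU,mixed,FN,-2.55,,synthetic illustrative study mean
eu_fn_study_e_synthetic,EU,mixed,FN,-2.62,,synthetic illustrative study mean
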