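study_id,region,sex_group,site,mean_t,sd_t,mean_bmd,n,age_mean,note
wong_aus_ffx,other,F,FN,-2.78,,,47,69.6,printed group mean
wong_aus_ffx,other,M,FN,-2.29,,,16,63.6,printed group mean
mros_msos_hk_cases,EA,F,FN,-2.59,1.00,,69,82.0,baseline T of women with hip fracture during follow-up
mros_msos_hk_cases,EA,M,FN,-1.97,0.72,,63,82.5,baseline T of men with hip fracture during follow-up
nhanes3_community,other,F,FN,-1.717,,,,,older community mean (non-fracture reference population)
nhanes3_community,other,M,FN,-1.241,,,,,older community mean (non-fracture reference population)
hk_community,EA,F,FN,-1.76,,,2000,72.5,cohort baseline community mean
hk_community,EA,M,FN,-1.25,,,2000,72.3,cohort baseline community mean
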