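name,value
dual_agreed_snakebite_deaths,2779
single_x20_candidates,105
single_x20_review_confirmed,54
other_pattern_candidates,136
other_pattern_review_confirmed,0
probable_snakebite_deaths,3020
included_snakebite_deaths,2833
ambulance_deaths_48h,359
ambulance_patients_transported,27509
total_bites_low_million,1.11
total_bites_high_million,1.77
envenomation_share,0.70
study_deaths_2001_2014_thousands,807.5
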