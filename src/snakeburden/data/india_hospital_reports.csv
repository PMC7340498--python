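region,burden_group,reported_bites,reported_deaths,in_hospital_fraction,est_total_deaths,est_hospital_deaths
Andhra Pradesh,higher,251.3,1.4,0.16,74.1,11.6
Bihar,higher,20.9,0.1,0.16,105.4,17.0
Odisha,higher,76.2,1.8,0.29,36.9,10.9
Madhya Pradesh,higher,28.3,1.1,0.22,64.4,14.1
Uttar Pradesh,higher,27.8,0.6,0.13,150.7,20.2
Rajasthan,higher,71.3,1.0,0.16,49.6,7.8
Gujarat,higher,45.7,0.8,0.27,38.6,10.5
Jharkhand,higher,8.5,0.1,0.12,20.0,2.5
Chhattisgarh,lower,16.7,0.3,0.17,14.3,2.4
Jammu & Kashmir,lower,18.4,0.0,0.26,5.9,1.5
Tamil Nadu,lower,106.6,0.5,0.28,36.0,10.0
Karnataka,lower,89.2,1.6,0.21,28.1,6.0
Maharashtra,lower,178.7,1.2,0.25,49.0,12.5
West Bengal,lower,208.9,3.4,0.41,38.9,15.9
Punjab,lower,9.1,0.2,0.10,14.2,1.4
Haryana,lower,14.3,0.1,0.16,8.5,1.3
Assam,lower,3.6,0.1,0.32,6.6,2.1
Northeastern states,lower,11.1,0.1,0.25,1.8,0.4
Kerala,lower,37.9,0.2,0.27,5.2,3.5
All other states,lower,77.8,0.8,0.24,11.1,2.7
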