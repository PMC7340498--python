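age_range,sex,deaths_thousands,lower,upper
0-14,male,149,134,154
0-14,female,176,160,180
0-14,both,325,294,334
15-29,male,109,102,111
15-29,female,88,82,89
15-29,both,197,184,199
30-69,male,290,269,303
30-69,female,253,232,260
70+,male,54,45,60
70+,female,48,44,50
70+,both,102,89,110
30-69,both,543,501,564
all,male,602,551,626
all,female,565,518,578
all,both,1167,1068,1204
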