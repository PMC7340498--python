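year,study_snakebite_deaths,study_all_cause_deaths,standardized_rate,rate_0_14,rate_15_29,rate_30_69,risk_before_70_pct,national_deaths_thousands
2001,199,41826,5.3,5.4,3.6,5.9,0.40,55.0
2002,183,41740,5.2,5.2,3.5,5.8,0.39,55.3
2003,179,38798,5.1,5.0,3.4,5.8,0.38,55.8
2004,190,37380,5.0,4.6,3.5,5.7,0.38,55.6
2005,244,46755,4.9,4.8,3.4,6.4,0.40,60.8
2006,214,47471,5.3,4.7,3.2,6.7,0.40,62.7
2007,225,48536,5.3,4.5,3.0,6.4,0.39,61.0
2008,215,47673,5.1,4.2,2.8,5.9,0.36,57.4
2009,183,47873,4.7,3.9,2.6,5.3,0.33,53.8
2010,200,45719,4.3,3.9,2.6,5.0,0.32,52.4
2011,185,46099,4.2,4.0,2.7,5.1,0.33,54.9
2012,227,46635,4.3,4.3,2.8,5.4,0.36,59.2
2013,214,45331,4.6,4.4,3.0,5.8,0.38,62.3
2014,175,29647,4.7,4.2,3.0,5.9,0.37,61.2
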