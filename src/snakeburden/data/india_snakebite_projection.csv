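year,national_deaths_thousands
2000,54.0
2015,62.3
2016,62.0
2017,61.4
2018,60.3
2019,59.8
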