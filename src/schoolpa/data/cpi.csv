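currency,year,index
NZD,2011,88.9
NZD,2017,96.0
NZD,2018,97.6
NZD,2019,100.0
NZD,2020,101.7
NZD,2021,105.7
AUD,2011,83.9
AUD,2019,100.0
AUD,2020,100.9
AUD,2021,103.8
GBP,2011,86.1
GBP,2019,100.0
GBP,2020,101.0
GBP,2021,103.6
EUR,2011,89.6
EUR,2019,100.0
EUR,2020,100.3
EUR,2021,102.8
USD,2011,88.0
USD,2019,100.0
USD,2020,101.2
USD,2021,106.0
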