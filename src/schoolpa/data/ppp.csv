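currency,year,factor_per_nzd
NZD,2019,1.0
AUD,2019,1.05328351
GBP,2019,0.47407274
EUR,2019,0.54800442
USD,2019,0.70778607
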