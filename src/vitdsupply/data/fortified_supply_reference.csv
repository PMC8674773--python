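country,period,natural_total_mean,natural_total_sd,natural_excl_ohd_mean,natural_excl_ohd_sd,fortified_total_mean,fortified_total_sd,fortified_excl_ohd_mean,fortified_excl_ohd_sd
Finland,2014-2017,7.9,0.2,7.2,0.2,10.8,0.2,10.4,0.2
USA,2014-2017,5.1,0.0,4.5,0.0,7.2,1.1,6.7,1.1
Canada,2014-2017,4.8,0.1,4.3,0.0,6.2,0.1,5.9,0.1
Sweden,2014-2017,6.0,0.1,5.3,0.1,6.3,0.3,5.8,0.3
Jordan,2014-2017,1.6,0.1,1.5,0.1,5.9,0.2,5.8,0.2
Kuwait,2014-2017,3.4,0.1,3.0,0.1,6.2,1.9,6.0,1.9
United Arab Emirates,2014-2017,3.9,0.2,3.5,0.1,6.7,1.9,6.5,1.9
Saudi Arabia,2014-2017,2.8,0.0,2.6,0.0,5.5,1.8,5.4,1.8
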