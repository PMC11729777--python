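year,total_days,available_days,total_hours,available_hours
2015,365,328,8760,7796
2016,366,309,8784,7421
2017,365,339,8760,8106
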