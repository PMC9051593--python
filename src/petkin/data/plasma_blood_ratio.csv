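time_min,value
5,1.76
30,1.80
60,1.79
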