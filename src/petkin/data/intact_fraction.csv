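time_min,value
5,0.981
30,0.952
60,0.901
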