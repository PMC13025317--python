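frequency,amplitude
0.001,0.038038225912388028
0.002,0.037806134917875739
0.0040000000000000001,0.036917455924957411
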