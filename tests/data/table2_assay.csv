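dose,tested,responders
30000,3,3
7500,4,4
1875,6,6
469,5,4
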