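# polynomial mean field acetonitrile U_vW (kJ/mol vs r in Å from truncation onset)
degree 4
domain 0.000000 10.000000
a_0 7.4319e-03
a_1 -3.8878
a_2 1.4842
a_3 -1.8302e-01
a_4 7.1257e-01
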