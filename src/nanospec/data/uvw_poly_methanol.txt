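# polynomial mean field methanol U_vW (kJ/mol vs r in Å from truncation onset)
degree 5
domain 0.000000 10.000000
a_0 -1.8081
a_1 -4.3732e-01
a_2 3.5936e-01
a_3 -6.2067e-01
a_4 4.2625e-03
a_5 -1.0404e-04
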