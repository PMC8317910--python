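# Synthetic standard life table following the Coale-Demeny "West" family's
# child-mortality age pattern (large infant share of under-five deaths,
# slow attrition after age 5). Constructed for this package -- NOT a
# transcription of the printed West tables; replace with a user-supplied
# standard (columns x,l) for production estimates against a specific level.
x,l
1,0.9330
2,0.9165
3,0.9070
5,0.8960
10,0.8800
15,0.8710
20,0.8600
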