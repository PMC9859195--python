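age,hand_m,hand_f,teeth_m,teeth_f,third_molar_m,third_molar_f,clavicle_m,clavicle_f
14,12,13,47,49,43,47,10,10
15,11,11,64,66,61,63,12,9
16,16,9,84,79,82,76,10,11
17,15,13,48,69,41,67,13,10
18,17,10,56,68,54,65,11,12
19,15,18,47,64,43,60,10,10
20,10,10,49,49,46,47,13,14
21,10,15,20,31,17,28,14,10
22,19,10,34,38,33,33,12,12
Total,125,109,449,513,420,486,105,98
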