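neuron,layer_703,layer_723,layer_787,note
r1,0,2,0,
l1,0,0,0,
r2,0,0,0,
l2,1,0,4,
r3,0,0,0,
l3,0,0,0,
r4,0,0,7,
l4,0,0,0,
r5,0,0,0,
l5,0,0,0,
r6,2,0,0,
l6,0,3,10,
r7,0,0,0,
l7,0,0,2,
r8,0,1,2,
l8,1,0,3,
r9,0,0,0,
l9,0,0,0,
r10,0,0,0,
l10,0,0,0,
r11,0,0,0,
l11,0,0,0,
r12,0,3,0,
l12,6,1,0,
r13,1,3,2,
l13,9,9,6,
r14,0,0,0,
l14,18,0,0,ambiguous
r15,0,0,0,
r16,0,0,0,
r17,0,0,0,
r18,0,0,0,
r19,0,0,0,
r20,0,0,0,
l15,0,0,0,
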