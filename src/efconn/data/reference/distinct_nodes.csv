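roi_id,initiation,inhibition,shifting,twoback
31,,1.0,,
36,,1.0,,
40,1.0,2.0,1.0,
44,1.0,1.0,,1.0
47,,1.0,,
48,2.0,2.0,1.0,
57,,1.0,,
59,,2.0,1.0,
60,,1.0,1.0,
61,1.0,1.0,1.0,
68,,1.0,,1.0
75,,4.0,,1.0
95,,1.0,,
96,,5.0,1.0,
99,,2.0,,
132,,2.0,,
135,,3.0,4.0,2.0
137,,1.0,,
138,,1.0,,
142,1.0,1.0,1.0,
149,1.0,1.0,,1.0
151,,1.0,,
153,1.0,1.0,1.0,
166,,1.0,,
167,,,2.0,
169,,,1.0,
173,,2.0,,
175,,,1.0,
176,,1.0,,
178,,,,1.0
193,,1.0,,
194,,5.0,,
198,,1.0,,
199,,1.0,,
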