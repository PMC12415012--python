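task,degree,fraction
initiation,1,0.4
inhibition,1,0.3461538
shifting,1,0.4736842
twoback,1,0.3518519
initiation,2,0.2363636
inhibition,2,0.2179487
shifting,2,0.1929825
twoback,2,0.2962963
initiation,3,0.1818182
inhibition,3,0.1153846
shifting,3,0.1403509
twoback,3,0.1481481
initiation,6,0.0545455
inhibition,4,0.0897436
shifting,4,0.1403509
twoback,4,0.1296296
initiation,5,0.0545455
inhibition,5,0.1153846
shifting,5,0.0175439
twoback,5,0.037037
initiation,7,0.0181818
inhibition,6,0.0512821
shifting,6,0.0350877
twoback,6,0.0185185
inhibition,7,0.0128205
twoback,7,0.0185185
inhibition,8,0.0512821
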