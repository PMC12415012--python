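task,roi_id,value
initiation,156,1.0
inhibition,66,1.0
shifting,45,1.0
twoback,45,1.0
initiation,147,1.0
inhibition,44,1.0
shifting,50,1.0
twoback,66,1.0
initiation,40,1.0
inhibition,47,1.0
shifting,66,1.0
twoback,44,1.0
initiation,45,1.0
inhibition,36,1.0
shifting,74,1.0
twoback,147,1.0
initiation,66,1.0
inhibition,95,1.0
shifting,40,1.0
twoback,170,1.0
initiation,170,1.0
inhibition,170,1.0
shifting,48,1.0
twoback,149,1.0
initiation,149,1.0
inhibition,149,1.0
shifting,147,1.0
twoback,189,0.0181818
initiation,50,1.0
inhibition,151,1.0
shifting,156,1.0
twoback,88,0.0172414
initiation,44,1.0
inhibition,138,1.0
shifting,170,1.0
twoback,81,0.015625
initiation,142,1.0
inhibition,193,1.0
shifting,183,1.0
twoback,192,0.0153846
initiation,189,0.0217391
inhibition,40,0.5
shifting,142,1.0
twoback,73,0.0151515
initiation,182,0.0196078
inhibition,99,0.5
shifting,153,1.0
twoback,134,0.0149254
initiation,90,0.0188679
inhibition,132,0.5
shifting,189,0.0181818
twoback,182,0.0144928
initiation,73,0.0188679
inhibition,31,0.3333333
shifting,88,0.0172414
twoback,72,0.0138889
initiation,72,0.0181818
inhibition,57,0.3333333
shifting,89,0.0172414
twoback,50,0.0138889
initiation,82,0.0181818
inhibition,142,0.3333333
shifting,192,0.0163934
twoback,82,0.0138889
initiation,81,0.0181818
inhibition,199,0.3333333
shifting,81,0.016129
twoback,71,0.0138889
initiation,33,0.0181818
inhibition,137,0.3333333
shifting,134,0.015873
twoback,187,0.0133333
initiation,134,0.0181818
inhibition,198,0.3333333
shifting,136,0.015873
twoback,90,0.0131579
initiation,181,0.0163934
inhibition,77,0.0049751
shifting,73,0.0149254
twoback,89,0.0131579
initiation,77,0.015873
inhibition,182,0.0048077
shifting,90,0.0147059
twoback,32,0.0131579
initiation,89,0.015873
inhibition,159,0.0048077
shifting,82,0.0142857
twoback,159,0.012987
initiation,48,0.015873
inhibition,186,0.0044248
shifting,34,0.0140845
twoback,136,0.012987
initiation,136,0.015873
inhibition,194,0.0044248
shifting,72,0.0140845
twoback,139,0.0126582
initiation,159,0.015625
inhibition,88,0.0044053
shifting,58,0.0140845
twoback,58,0.0121951
initiation,179,0.015625
inhibition,82,0.004329
shifting,139,0.0140845
twoback,160,0.0120482
initiation,186,0.0153846
inhibition,81,0.004329
shifting,71,0.0138889
twoback,79,0.0119048
initiation,79,0.0153846
inhibition,195,0.0042735
shifting,33,0.0136986
twoback,38,0.0119048
initiation,88,0.0153846
inhibition,72,0.0042553
shifting,32,0.0136986
twoback,165,0.0117647
initiation,78,0.0153846
inhibition,58,0.0041494
shifting,159,0.0136986
twoback,33,0.0116279
initiation,71,0.0153846
inhibition,33,0.0041152
shifting,182,0.0133333
twoback,179,0.0114943
initiation,139,0.0149254
inhibition,73,0.0040816
shifting,179,0.012987
twoback,34,0.0113636
initiation,192,0.0142857
inhibition,96,0.0040161
shifting,160,0.0126582
twoback,135,0.011236
initiation,140,0.0140845
inhibition,189,0.004
shifting,38,0.0123457
twoback,156,0.010989
initiation,32,0.0136986
inhibition,79,0.0039526
shifting,181,0.0123457
twoback,178,0.010989
initiation,195,0.0136986
inhibition,75,0.0039216
shifting,187,0.0114943
twoback,52,0.0106383
initiation,187,0.0135135
inhibition,78,0.0038911
shifting,135,0.0114943
twoback,181,0.0105263
initiation,160,0.0135135
inhibition,192,0.0038168
shifting,52,0.0113636
twoback,195,0.0105263
initiation,133,0.0133333
inhibition,52,0.0038023
shifting,91,0.0113636
twoback,80,0.0104167
initiation,91,0.012987
inhibition,134,0.0037879
shifting,80,0.0111111
twoback,186,0.009901
initiation,38,0.0126582
inhibition,80,0.0037736
shifting,133,0.010989
twoback,91,0.0098039
initiation,52,0.0123457
inhibition,139,0.0036232
shifting,79,0.0107527
twoback,140,0.0093458
initiation,153,0.0121951
inhibition,136,0.0035971
shifting,195,0.0107527
twoback,68,0.0090909
initiation,58,0.0120482
inhibition,97,0.0035842
shifting,165,0.0105263
twoback,75,0.0090909
initiation,80,0.0120482
inhibition,74,0.0035587
shifting,150,0.009901
twoback,133,0.009009
initiation,34,0.0120482
inhibition,181,0.0035461
shifting,140,0.0097087
twoback,157,0.0088496
initiation,97,0.0117647
inhibition,187,0.0035461
shifting,157,0.0095238
twoback,150,0.0084034
initiation,74,0.0117647
inhibition,160,0.0035461
shifting,60,0.009009
twoback,97,0.0083333
initiation,150,0.0108696
inhibition,165,0.0035461
shifting,59,0.009009
twoback,78,0.0081967
initiation,37,0.0107527
inhibition,133,0.0035211
shifting,186,0.0088496
twoback,77,0.0079365
initiation,157,0.01
inhibition,90,0.0034843
shifting,96,0.0086957
twoback,37,0.0075758
initiation,165,0.0095238
inhibition,89,0.0034364
shifting,97,0.008547
twoback,46,0.0072464
initiation,183,0.0093458
inhibition,135,0.0034247
shifting,46,0.0084746
twoback,183,0.0068966
initiation,46,0.009009
inhibition,50,0.0032787
shifting,61,0.0084746
twoback,74,0.0058824
initiation,61,0.009009
inhibition,48,0.0032787
shifting,37,0.007874
inhibition,71,0.0032573
shifting,77,0.0072993
inhibition,173,0.0032258
shifting,78,0.0072993
inhibition,32,0.0032154
inhibition,183,0.0032051
inhibition,38,0.0031949
inhibition,34,0.0031949
inhibition,157,0.003125
inhibition,179,0.0030303
inhibition,37,0.0030211
inhibition,156,0.002924
inhibition,176,0.002907
inhibition,59,0.0028818
inhibition,60,0.0028653
inhibition,153,0.0027624
inhibition,140,0.0027322
inhibition,68,0.0027248
inhibition,91,0.0026525
inhibition,166,0.0024752
inhibition,150,0.0023474
inhibition,45,0.002079
inhibition,46,0.0020704
inhibition,61,0.0020704
inhibition,147,0.0018587
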