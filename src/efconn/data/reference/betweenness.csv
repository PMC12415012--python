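task,roi_id,value
initiation,189,138.0
inhibition,159,895.3666667
shifting,189,101.5
twoback,189,132.0
initiation,182,84.151826
inhibition,77,848.1891273
shifting,134,89.468074
twoback,182,132.0
initiation,90,81.5
inhibition,189,572.5642857
shifting,182,88.648268
twoback,73,116.2
initiation,73,72.513161
inhibition,182,550.4220114
shifting,136,75.97132
twoback,134,107.616667
initiation,72,68.605463
inhibition,88,363.0404762
shifting,72,73.452381
twoback,79,105.0
initiation,179,64.0
inhibition,179,312.9166667
shifting,192,72.5
twoback,88,96.5
initiation,186,61.710859
inhibition,58,265.3270125
shifting,73,69.377489
twoback,186,91.0
initiation,136,59.64667
inhibition,91,265.0
shifting,81,69.0
twoback,192,84.5
initiation,159,55.0
inhibition,90,263.1595238
shifting,79,66.0
twoback,81,79.0
initiation,33,54.013823
inhibition,72,227.7273555
shifting,90,65.0
twoback,72,70.9
initiation,91,51.0
inhibition,150,221.0
shifting,179,56.0
twoback,159,53.0
initiation,81,45.0
inhibition,82,189.8714286
shifting,58,50.816991
twoback,179,51.5
initiation,82,45.0
inhibition,81,189.8714286
shifting,135,47.916667
twoback,38,50.733333
initiation,150,37.0
inhibition,186,180.5773489
shifting,186,47.0
twoback,165,50.516667
initiation,134,33.551963
inhibition,89,168.8166667
shifting,159,47.0
twoback,78,48.0
initiation,140,24.714596
inhibition,135,167.0
shifting,38,46.708333
twoback,91,36.0
initiation,74,22.0
inhibition,194,153.6120443
shifting,91,45.0
twoback,90,30.0
initiation,58,22.0
inhibition,75,126.5622013
shifting,34,40.60303
twoback,89,30.0
initiation,48,19.0
inhibition,134,125.977697
shifting,88,35.0
twoback,136,28.483333
initiation,52,19.0
inhibition,139,114.5426742
shifting,89,35.0
twoback,33,27.733333
initiation,139,17.64667
inhibition,192,111.102381
shifting,32,34.75184
twoback,195,25.0
initiation,77,14.227234
inhibition,195,96.4863525
shifting,150,33.0
twoback,140,25.0
initiation,181,13.160497
inhibition,33,76.6583392
shifting,139,30.957251
twoback,183,25.0
initiation,195,8.555808
inhibition,73,63.8258992
shifting,33,28.289935
twoback,32,22.9
initiation,78,7.643687
inhibition,45,57.0
shifting,133,24.791667
twoback,58,22.8
initiation,79,7.643687
inhibition,52,57.0
shifting,195,24.0
twoback,50,19.0
initiation,38,6.861111
inhibition,48,57.0
shifting,140,24.0
twoback,52,19.0
initiation,89,6.5
inhibition,59,57.0
shifting,82,17.0
twoback,71,19.0
initiation,32,5.341834
inhibition,173,57.0
shifting,52,17.0
twoback,150,19.0
initiation,192,3.0
inhibition,96,54.0447632
shifting,181,7.246753
twoback,139,18.866667
initiation,133,2.861111
inhibition,136,49.6574909
shifting,77,0.0
twoback,82,5.5
initiation,97,1.4
inhibition,78,48.6184711
shifting,46,0.0
twoback,187,4.0
initiation,34,0.75
inhibition,79,33.2078878
shifting,45,0.0
twoback,34,2.733333
initiation,80,0.0
inhibition,38,27.9546775
shifting,80,0.0
twoback,135,1.516667
initiation,187,0.0
inhibition,34,27.9546775
shifting,97,0.0
twoback,181,1.0
initiation,44,0.0
inhibition,50,20.2404762
shifting,50,0.0
twoback,77,0.0
initiation,88,0.0
inhibition,165,18.7331633
shifting,66,0.0
twoback,46,0.0
initiation,46,0.0
inhibition,181,16.4903546
shifting,74,0.0
twoback,80,0.0
initiation,71,0.0
inhibition,74,13.4422031
shifting,96,0.0
twoback,45,0.0
initiation,45,0.0
inhibition,133,12.2607623
shifting,78,0.0
twoback,97,0.0
initiation,37,0.0
inhibition,32,10.9993036
shifting,60,0.0
twoback,66,0.0
initiation,50,0.0
inhibition,37,6.8630962
shifting,37,0.0
twoback,74,0.0
initiation,147,0.0
inhibition,156,3.5833333
shifting,40,0.0
twoback,44,0.0
initiation,157,0.0
inhibition,140,3.1626206
shifting,48,0.0
twoback,68,0.0
initiation,66,0.0
inhibition,183,2.0774802
shifting,59,0.0
twoback,37,0.0
initiation,40,0.0
inhibition,97,1.6249851
shifting,61,0.0
twoback,75,0.0
initiation,61,0.0
inhibition,40,1.0
shifting,71,0.0
twoback,147,0.0
initiation,156,0.0
inhibition,99,1.0
shifting,147,0.0
twoback,156,0.0
initiation,170,0.0
inhibition,132,1.0
shifting,187,0.0
twoback,157,0.0
initiation,160,0.0
inhibition,187,0.7333333
shifting,156,0.0
twoback,170,0.0
initiation,183,0.0
inhibition,160,0.7333333
shifting,160,0.0
twoback,160,0.0
initiation,149,0.0
inhibition,46,0.0
shifting,157,0.0
twoback,149,0.0
initiation,142,0.0
inhibition,80,0.0
shifting,170,0.0
twoback,133,0.0
initiation,165,0.0
inhibition,66,0.0
shifting,183,0.0
twoback,178,0.0
initiation,153,0.0
inhibition,44,0.0
shifting,165,0.0
inhibition,71,0.0
shifting,142,0.0
inhibition,31,0.0
shifting,153,0.0
inhibition,47,0.0
inhibition,61,0.0
inhibition,36,0.0
inhibition,57,0.0
inhibition,60,0.0
inhibition,68,0.0
inhibition,95,0.0
inhibition,147,0.0
inhibition,170,0.0
inhibition,157,0.0
inhibition,142,0.0
inhibition,149,0.0
inhibition,153,0.0
inhibition,166,0.0
inhibition,199,0.0
inhibition,151,0.0
inhibition,138,0.0
inhibition,137,0.0
inhibition,176,0.0
inhibition,193,0.0
inhibition,198,0.0
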