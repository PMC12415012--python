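task,roi_id,value
initiation,186,286.0
inhibition,186,365.0
shifting,139,208.0
twoback,73,205.0
initiation,189,205.0
inhibition,189,300.0
shifting,136,187.0
twoback,134,174.0
initiation,182,186.0
inhibition,182,291.0
shifting,73,185.0
twoback,189,167.0
initiation,139,168.0
inhibition,139,275.0
shifting,189,182.0
twoback,139,158.0
initiation,73,162.0
inhibition,159,244.0
shifting,186,176.0
twoback,136,134.0
initiation,77,155.0
inhibition,73,233.0
shifting,134,176.0
twoback,186,133.0
initiation,72,152.0
inhibition,134,232.0
shifting,33,168.0
twoback,88,132.0
initiation,33,142.0
inhibition,33,231.0
shifting,182,136.0
twoback,182,132.0
initiation,79,139.0
inhibition,72,227.0
shifting,88,125.0
twoback,33,125.0
initiation,134,124.0
inhibition,79,210.0
shifting,77,117.0
twoback,179,108.0
initiation,159,122.0
inhibition,77,203.0
shifting,72,117.0
twoback,72,102.0
initiation,38,110.0
inhibition,88,186.0
shifting,79,115.0
twoback,38,97.0
initiation,136,106.0
inhibition,181,162.0
shifting,34,114.0
twoback,79,95.0
initiation,88,102.0
inhibition,136,161.0
shifting,179,114.0
twoback,77,85.0
initiation,150,93.0
inhibition,38,159.0
shifting,159,113.0
twoback,90,84.0
initiation,195,89.0
inhibition,90,156.0
shifting,38,111.0
twoback,159,83.0
initiation,90,86.0
inhibition,179,151.0
shifting,150,103.0
twoback,58,78.0
initiation,179,86.0
inhibition,150,134.0
shifting,90,97.0
twoback,150,72.0
initiation,181,85.0
inhibition,81,131.0
shifting,181,85.0
twoback,192,62.0
initiation,82,82.0
inhibition,195,125.0
shifting,82,84.0
twoback,165,62.0
initiation,97,75.0
inhibition,82,123.0
shifting,58,83.0
twoback,34,61.0
initiation,81,74.0
inhibition,34,113.0
shifting,46,79.0
twoback,52,58.0
initiation,46,68.0
inhibition,97,112.0
shifting,32,74.0
twoback,181,58.0
initiation,140,59.0
inhibition,89,99.0
shifting,195,68.0
twoback,46,54.0
initiation,78,54.0
inhibition,52,98.0
shifting,52,65.0
twoback,81,52.0
initiation,147,54.0
inhibition,78,94.0
shifting,192,65.0
twoback,82,49.0
initiation,45,54.0
inhibition,32,93.0
shifting,45,64.0
twoback,50,46.0
initiation,89,54.0
inhibition,192,93.0
shifting,147,64.0
twoback,195,46.0
initiation,80,53.0
inhibition,46,87.0
shifting,135,64.0
twoback,89,45.0
initiation,52,53.0
inhibition,80,83.0
shifting,80,59.0
twoback,91,45.0
initiation,34,51.0
inhibition,140,83.0
shifting,89,56.0
twoback,80,43.0
initiation,192,47.0
inhibition,45,80.0
shifting,97,55.0
twoback,140,42.0
initiation,32,46.0
inhibition,50,80.0
shifting,133,55.0
twoback,45,39.0
initiation,187,42.0
inhibition,187,80.0
shifting,81,54.0
twoback,147,39.0
initiation,156,38.0
inhibition,58,76.0
shifting,187,54.0
twoback,187,39.0
initiation,50,38.0
inhibition,156,76.0
shifting,50,53.0
twoback,32,36.0
initiation,91,38.0
inhibition,133,70.0
shifting,156,53.0
twoback,97,35.0
initiation,74,37.0
inhibition,91,68.0
shifting,140,48.0
twoback,156,34.0
initiation,160,28.0
inhibition,96,68.0
shifting,91,43.0
twoback,78,30.0
initiation,170,28.0
inhibition,147,68.0
shifting,160,26.0
twoback,157,30.0
initiation,66,28.0
inhibition,74,63.0
shifting,66,25.0
twoback,183,29.0
initiation,58,25.0
inhibition,160,62.0
shifting,157,25.0
twoback,66,28.0
initiation,133,25.0
inhibition,183,59.0
shifting,170,25.0
twoback,170,28.0
initiation,183,22.0
inhibition,194,59.0
shifting,74,22.0
twoback,135,27.0
initiation,48,21.0
inhibition,66,53.0
shifting,183,22.0
twoback,160,24.0
initiation,157,17.0
inhibition,170,53.0
shifting,96,21.0
twoback,71,21.0
initiation,37,14.0
inhibition,75,47.0
shifting,78,20.0
twoback,74,18.0
initiation,44,13.0
inhibition,165,42.0
shifting,165,20.0
twoback,44,17.0
initiation,149,13.0
inhibition,135,42.0
shifting,60,17.0
twoback,149,17.0
initiation,142,12.0
inhibition,37,36.0
shifting,37,15.0
twoback,68,15.0
initiation,40,12.0
inhibition,48,35.0
shifting,40,11.0
twoback,37,12.0
initiation,165,12.0
inhibition,59,33.0
shifting,48,11.0
twoback,75,12.0
initiation,153,11.0
inhibition,40,31.0
shifting,59,11.0
twoback,133,11.0
initiation,61,10.0
inhibition,157,31.0
shifting,142,11.0
twoback,178,10.0
initiation,71,10.0
inhibition,173,25.0
shifting,153,11.0
inhibition,132,24.0
shifting,61,10.0
inhibition,99,22.0
shifting,71,10.0
inhibition,142,21.0
inhibition,44,20.0
inhibition,149,20.0
inhibition,153,16.0
inhibition,71,15.0
inhibition,31,14.0
inhibition,166,14.0
inhibition,199,12.0
inhibition,47,11.0
inhibition,61,11.0
inhibition,151,11.0
inhibition,36,10.0
inhibition,57,10.0
inhibition,60,10.0
inhibition,68,10.0
inhibition,95,10.0
inhibition,138,10.0
inhibition,137,10.0
inhibition,176,10.0
inhibition,193,10.0
inhibition,198,10.0
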