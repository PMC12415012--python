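task,roi_id,value
initiation,189,7.0
inhibition,72,8.0
shifting,134,6.0
twoback,134,7.0
initiation,72,6.0
inhibition,189,8.0
shifting,136,6.0
twoback,73,6.0
initiation,182,6.0
inhibition,134,8.0
shifting,189,5.0
twoback,189,5.0
initiation,186,6.0
inhibition,182,8.0
shifting,73,4.0
twoback,136,5.0
initiation,73,5.0
inhibition,139,7.0
shifting,33,4.0
twoback,33,4.0
initiation,33,5.0
inhibition,33,6.0
shifting,34,4.0
twoback,72,4.0
initiation,136,5.0
inhibition,186,6.0
shifting,72,4.0
twoback,38,4.0
initiation,139,4.0
inhibition,159,6.0
shifting,58,4.0
twoback,58,4.0
initiation,134,4.0
inhibition,136,6.0
shifting,32,4.0
twoback,139,4.0
initiation,159,4.0
inhibition,77,5.0
shifting,139,4.0
twoback,182,4.0
initiation,77,3.0
inhibition,88,5.0
shifting,135,4.0
twoback,165,4.0
initiation,195,3.0
inhibition,90,5.0
shifting,38,3.0
twoback,88,3.0
initiation,82,3.0
inhibition,73,5.0
shifting,81,3.0
twoback,34,3.0
initiation,81,3.0
inhibition,32,5.0
shifting,186,3.0
twoback,81,3.0
initiation,140,3.0
inhibition,58,5.0
shifting,150,3.0
twoback,32,3.0
initiation,38,3.0
inhibition,96,5.0
shifting,182,3.0
twoback,186,3.0
initiation,150,3.0
inhibition,181,5.0
shifting,159,3.0
twoback,179,3.0
initiation,90,3.0
inhibition,194,5.0
shifting,192,3.0
twoback,159,3.0
initiation,32,3.0
inhibition,79,4.0
shifting,133,3.0
twoback,192,3.0
initiation,181,3.0
inhibition,38,4.0
shifting,88,2.0
twoback,90,2.0
initiation,78,2.0
inhibition,34,4.0
shifting,90,2.0
twoback,79,2.0
initiation,79,2.0
inhibition,75,4.0
shifting,79,2.0
twoback,50,2.0
initiation,179,2.0
inhibition,150,4.0
shifting,82,2.0
twoback,89,2.0
initiation,97,2.0
inhibition,195,4.0
shifting,89,2.0
twoback,52,2.0
initiation,133,2.0
inhibition,133,4.0
shifting,52,2.0
twoback,82,2.0
initiation,74,2.0
inhibition,82,3.0
shifting,91,2.0
twoback,91,2.0
initiation,192,2.0
inhibition,78,3.0
shifting,179,2.0
twoback,78,2.0
initiation,34,2.0
inhibition,81,3.0
shifting,181,2.0
twoback,71,2.0
initiation,52,2.0
inhibition,89,3.0
shifting,195,2.0
twoback,150,2.0
initiation,89,2.0
inhibition,179,3.0
shifting,140,2.0
twoback,181,2.0
initiation,91,2.0
inhibition,140,3.0
shifting,77,1.0
twoback,195,2.0
initiation,58,2.0
inhibition,192,3.0
shifting,46,1.0
twoback,140,2.0
initiation,48,2.0
inhibition,165,3.0
shifting,45,1.0
twoback,187,2.0
initiation,147,1.0
inhibition,135,3.0
shifting,80,1.0
twoback,183,2.0
initiation,44,1.0
inhibition,97,2.0
shifting,97,1.0
twoback,135,2.0
initiation,61,1.0
inhibition,45,2.0
shifting,50,1.0
twoback,77,1.0
initiation,183,1.0
inhibition,52,2.0
shifting,66,1.0
twoback,46,1.0
initiation,170,1.0
inhibition,50,2.0
shifting,74,1.0
twoback,80,1.0
initiation,40,1.0
inhibition,74,2.0
shifting,96,1.0
twoback,45,1.0
initiation,160,1.0
inhibition,91,2.0
shifting,78,1.0
twoback,97,1.0
initiation,50,1.0
inhibition,40,2.0
shifting,60,1.0
twoback,66,1.0
initiation,66,1.0
inhibition,37,2.0
shifting,37,1.0
twoback,74,1.0
initiation,156,1.0
inhibition,48,2.0
shifting,40,1.0
twoback,44,1.0
initiation,187,1.0
inhibition,59,2.0
shifting,48,1.0
twoback,68,1.0
initiation,142,1.0
inhibition,99,2.0
shifting,59,1.0
twoback,37,1.0
initiation,80,1.0
inhibition,187,2.0
shifting,61,1.0
twoback,75,1.0
initiation,45,1.0
inhibition,156,2.0
shifting,71,1.0
twoback,147,1.0
initiation,46,1.0
inhibition,160,2.0
shifting,147,1.0
twoback,156,1.0
initiation,88,1.0
inhibition,183,2.0
shifting,187,1.0
twoback,157,1.0
initiation,37,1.0
inhibition,173,2.0
shifting,156,1.0
twoback,170,1.0
initiation,71,1.0
inhibition,132,2.0
shifting,160,1.0
twoback,160,1.0
initiation,157,1.0
inhibition,46,1.0
shifting,157,1.0
twoback,149,1.0
initiation,149,1.0
inhibition,80,1.0
shifting,170,1.0
twoback,133,1.0
initiation,165,1.0
inhibition,66,1.0
shifting,183,1.0
twoback,178,1.0
initiation,153,1.0
inhibition,44,1.0
shifting,165,1.0
inhibition,71,1.0
shifting,142,1.0
inhibition,31,1.0
shifting,153,1.0
inhibition,47,1.0
inhibition,61,1.0
inhibition,36,1.0
inhibition,57,1.0
inhibition,60,1.0
inhibition,68,1.0
inhibition,95,1.0
inhibition,147,1.0
inhibition,170,1.0
inhibition,157,1.0
inhibition,142,1.0
inhibition,149,1.0
inhibition,153,1.0
inhibition,166,1.0
inhibition,199,1.0
inhibition,151,1.0
inhibition,138,1.0
inhibition,137,1.0
inhibition,176,1.0
inhibition,193,1.0
inhibition,198,1.0
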