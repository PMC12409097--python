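element,isotope,offset,mass,abundance
C,12C,0,12.0,0.9893
C,13C,1,13.00335483507,0.0107
H,1H,0,1.00782503207,0.999885
H,2H,1,2.01410177812,0.000115
N,14N,0,14.0030740048,0.99636
N,15N,1,15.0001088989,0.00364
O,16O,0,15.9949146196,0.99757
O,17O,1,16.9991317012,0.00038
O,18O,2,17.9991596129,0.00205
Si,28Si,0,27.9769265347,0.92223
Si,29Si,1,28.9764946649,0.04685
Si,30Si,2,29.973770136,0.03092
S,32S,0,31.9720711744,0.9499
S,33S,1,32.9714589098,0.0075
S,34S,2,33.967867004,0.0425
S,36S,4,35.96708071,0.0001
P,31P,0,30.9737619984,1.0
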