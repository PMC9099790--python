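# Fitted equivalent-circuit parameters for lidocaine on API 5L steel in 3% NaCl.
# conc_ppm=0 is the uninhibited blank (Randles circuit: no film branch).
# rs/rct/rmol/rtotal in ohm cm^2; cdl/cf in uF/cm^2; ie_printed is the
# published efficiency column, kept for comparison only.
conc_ppm,rs,n_cpe,cdl,rct,cf,n2,rmol,rtotal,ie_printed
0,6,0.800,2960,127,,,,,
10,8.24,0.80,181.3,102.00,4034.0,0.8,28.70,130.70,3.2
20,10.53,0.77,187.5,404.10,622.2,0.52,337.90,742.00,83.0
50,24.66,0.85,90.3,1493.00,40.7,0.49,151.70,1644.70,92.3
100,24.29,0.84,51.9,1522.00,26.0,0.48,157.00,1679.00,92.5
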