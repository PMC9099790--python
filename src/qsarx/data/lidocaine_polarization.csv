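# Tafel-analysis parameters for lidocaine on API 5L steel in 3% NaCl.
# ecorr in mV vs Ag/AgCl(sat); icorr in uA/cm^2; ba/bc in mV/decade
# (bc is the cathodic slope magnitude); ie_printed is the published
# efficiency column, kept for comparison only.
conc_ppm,ecorr,icorr,ba,bc,ie_printed
0,-804.7,67.4,159.5,173,
10,-909.7,65.0,146.6,161.5,3.4
20,-709.6,4.9,104.5,204.1,92.6
50,-907.7,7.4,170.5,60.3,89.0
100,-916.5,8.2,187.8,68.2,87.4
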