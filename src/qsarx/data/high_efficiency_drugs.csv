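# Descriptor values and predicted inhibition efficiencies for the ten drugs
# in the published high-efficiency cohort (IE% above 95).  Energies in eV;
# omega is on the table-compatible (chi/4) scale; ie_obs is the model-predicted IE%.
name,pka,e_homo,e_lumo,omega,delta_n,ie_obs
Deserpidine,6.68,-4.92,-2.42,0.92,1.33,95.29
Daunorubicin,8.20,-5.87,-4.01,1.23,1.11,96.67
Dipyridamole,6.40,-4.34,-1.83,0.77,1.55,97.28
Doxorubicin,9.46,-5.86,-4.00,1.23,1.12,97.40
Amphotericin B,3.58,-5.27,-3.29,1.07,1.37,97.55
Minocycline,2.30,-5.32,-3.42,1.09,1.38,97.58
Acepromazine,9.30,-4.92,-2.53,0.93,1.37,97.73
Cephaloridine,3.40,-5.31,-3.43,1.09,1.40,98.57
Mercaptopurine,7.80,-5.03,-2.83,0.98,1.40,98.66
Rifampicin,1.70,-4.86,-2.81,0.96,1.55,98.71
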