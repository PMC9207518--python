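# Molar extinction coefficients of human oxy- and deoxy-hemoglobin,
# compiled from standard published tabulations and converted to the
# natural-log convention in mm^-1 mM^-1:
#   mu_a [mm^-1] = eps_HbO2 * StO2 * cTHb + eps_Hb * (1 - StO2) * cTHb,
# with cTHb in mM.
wavelength_nm	eps_hbo2	eps_hb
580	11.539	8.5257
590	3.1091	5.9878
600	0.73696	3.3801
610	0.34683	2.1747
620	0.21694	1.4991
630	0.14048	1.1858
640	0.10179	1.0007
650	0.084750	0.86363
660	0.073696	0.74318
670	0.067708	0.64369
680	0.064023	0.55433
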