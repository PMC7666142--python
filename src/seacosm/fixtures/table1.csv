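variable,winter,spring,summer,fall
date,2017/2/20,2017/4/25,2017/7/4,2017/11/6
temperature_c,12.8,14.8,23.1,19.5
salinity,38.01,38.06,38.02,37.70
secchi_depth_m,8,20,20,19
surface_par_umol_photons_m2_s,546,569,789,224
chlorophyll_a_ug_l,1.20,0.43,0.13,0.46
po4_um,0.044,0.028,0.015,0.025
nh4_um,0.214,1.567,0.431,0.200
no2_um,0.280,0.119,0.036,0.040
no3_um,1.167,0.357,0.034,0.155
sio4_um,1.507,1.194,0.690,0.663
doc_um,63.8,65.7,86.2,77.9
prokaryotic_abundance_cells_ml,1.04e6,1.01e6,7.28e5,1.58e6
bacterial_production_ugc_l_day,2.57,3.03,4.62,1.34
leu_specific_growth_rate_day,0.033,0.047,0.139,0.032
pct_hna_cells,61.6,48.0,46.6,26.9
hnf_abundance_cells_ml,1.24e3,1.65e3,1.49e3,1.03e3
synechococcus_cells_ml,1.06e4,4.43e4,1.70e4,3.45e4
picoeukaryote_cells_ml,1.61e4,6.44e3,1.27e3,2.38e3
viral_abundance_ml,9.89e6,1.16e6,7.75e6,1.90e7
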