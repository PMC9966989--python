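nutrient,lack_of_vigor_low,lack_of_vigor_high,lack_of_vigor_p,irritability_low,irritability_high,irritability_p,fatigue_low,fatigue_high,fatigue_p,somatic_low,somatic_high,somatic_p,printed_cutoff
K_mg,2436.8,2538.5,0.007,2531.0,2349.1,0.000,2544.8,2353.8,0.000,2507.0,2441.6,0.129,2500
Mg_mg,265.3,278.3,0.002,276.5,256.2,0.000,278.1,256.5,0.000,274.4,265.8,0.064,270
P_mg,1071.4,1114.5,0.005,1106.9,1045.1,0.001,1107.4,1054.4,0.001,1100.1,1074.8,0.143,1100
Fe_mg,8.07,8.38,0.006,8.36,7.80,0.004,8.34,7.93,0.000,8.22,8.16,0.611,8.1
Zn_mg,8.29,8.72,0.014,8.59,8.16,0.006,8.58,8.26,0.035,8.57,8.34,0.775,8.5
Cu_mg,1.14,1.18,0.034,1.18,1.10,0.002,1.18,1.11,0.000,1.17,1.14,0.207,1.18
VA_ugRE,574.0,564.1,0.003,569.9,570.2,0.010,565.8,577.8,0.000,609.9,520.2,0.053,570
bCx_ug,221.0,261.7,0.003,261.2,179.9,0.004,274.5,168.8,0.000,253.6,217.4,0.011,260
bCt_ug,3045.1,3294.1,0.040,3240.8,2914.5,0.005,3272.1,2910.9,0.000,3173.0,3111.3,0.100,3200
VB1_mg,0.96,0.99,0.040,0.99,0.94,0.008,0.99,0.95,0.027,0.99,0.96,0.308,0.97
Niacin_mgNE,31.86,33.53,0.001,33.22,30.89,0.000,33.27,31.18,0.000,33.23,31.67,0.025,33
VB6_mg,1.21,1.28,0.003,1.27,1.16,0.000,1.28,1.16,0.000,1.26,1.21,0.057,1.25
FA_ug,295.1,316.1,0.001,311.8,283.6,0.000,311.9,288.1,0.000,311.2,294.1,0.026,300
PA_mg,5.98,6.22,0.018,6.18,5.82,0.000,6.20,5.84,0.000,6.17,5.96,0.072,6.0
TDF_g,18.06,18.90,0.009,18.84,17.32,0.000,18.78,17.68,0.000,18.69,18.03,0.038,18
IDF_g,11.63,12.23,0.007,12.24,10.97,0.000,12.19,11.27,0.000,12.06,11.64,0.073,12
Biotin_ug,40.60,42.66,0.003,42.07,39.88,0.003,42.23,39.93,0.000,42.48,40.12,0.065,42
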