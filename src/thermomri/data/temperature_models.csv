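region,parameter,variant,a,ci_a,b,ci_b,r2_adj,p_value,p_is_upper_bound,delta_star_pct,delta_double_star_pct
white_matter,T1,with_invivo,581.5,35.2,0.0,1.7,-0.03,0.514,False,6.6,
white_matter,T1,without_invivo,566.9,64.9,1.2,4.7,-0.05,0.637,False,,-6.6
white_matter,T2,with_invivo,105.2,3.3,-0.5,0.2,0.73,0.001,True,-1.0,
white_matter,T2,without_invivo,105.4,5.6,-0.6,0.4,0.41,0.005,False,,21.6
white_matter,T2star,with_invivo,31.7,3.0,0.4,0.1,0.63,0.001,True,-22.5,
white_matter,T2star,without_invivo,36.1,4.1,0.1,0.3,-0.06,0.733,False,,-4.6
white_matter,MD,with_invivo,-4.1e-05,7.2e-05,1.6e-05,3.2e-06,0.85,0.001,True,-56.6,
white_matter,MD,without_invivo,1.0e-04,4.2e-05,4.3e-06,2.9e-06,0.45,0.003,False,,-54.3
white_matter,FA,with_invivo,3.9e-01,3.1e-02,4.63e-04,1.4e-03,-0.02,0.422,False,-1.9,
white_matter,FA,without_invivo,4.0e-01,2.3e-02,7.2e-05,1.0e-03,-0.07,0.846,False,,-0.6
cerebral_cortex,T1,with_invivo,902.8,73.1,3.8,3.6,0.21,0.024,False,14.9,
cerebral_cortex,T1,without_invivo,846.4,115.7,8.7,8.4,0.19,0.050,False,,-24.3
cerebral_cortex,T2,with_invivo,124.8,10.6,-0.5,0.5,0.14,0.055,False,1.9,
cerebral_cortex,T2,without_invivo,124.3,18.7,-0.5,1.4,0.03,0.252,False,,15.3
cerebral_cortex,T2star,with_invivo,32.5,3.4,0.3,0.2,0.34,0.004,False,-17.4,
cerebral_cortex,T2star,without_invivo,35.6,5.5,0.03,0.41,-0.07,0.838,False,,-3.1
cerebral_cortex,MD,with_invivo,-1.8e-05,8.2e-05,2.2e-05,3.5e-06,0.87,0.001,True,-47.4,
cerebral_cortex,MD,without_invivo,1.4e-04,6.8e-05,7.7e-06,5.0e-06,0.48,0.002,False,,-58.8
cerebral_cortex,FA,with_invivo,2.1e-01,2.4e-02,-8.8e-04,1.3e-03,0.21,0.023,False,80.7,
cerebral_cortex,FA,without_invivo,1.8e-01,2.5e-02,1.9e-03,1.8e-03,0.09,0.143,False,,-24.3
deep_gray_matter,T1,with_invivo,569.5,36.7,4.6,1.7,0.68,0.001,True,-2.8,
deep_gray_matter,T1,without_invivo,578.2,61.8,3.9,4.2,0.27,0.023,False,,-17.6
deep_gray_matter,T2,with_invivo,90.6,5.6,-0.2,0.3,0.07,0.137,False,1.8,
deep_gray_matter,T2,without_invivo,89.6,9.6,-0.1,0.7,-0.03,0.475,False,,4.4
deep_gray_matter,T2star,with_invivo,22.4,3.2,0.4,0.2,0.62,0.001,True,-24.3,
deep_gray_matter,T2star,without_invivo,26.2,4.6,0.11,0.33,-0.04,0.507,False,,-11.5
deep_gray_matter,MD,with_invivo,-4.8e-06,4.4e-05,1.6e-05,2.8e-06,0.86,0.001,True,-49.8,
deep_gray_matter,MD,without_invivo,1.2e-04,4.8e-05,5.2e-06,3.4e-06,0.40,0.005,False,,-53.6
deep_gray_matter,FA,with_invivo,4.3e-01,4.4e-02,-2.6e-03,2.2e-03,0.27,0.011,False,48.7,
deep_gray_matter,FA,without_invivo,3.8e-01,5.6e-02,1.8e-03,3.9e-03,-0.03,0.490,False,,-12.9
globus_pallidus,T1,with_invivo,524.6,17.3,3.0,0.7,0.78,0.001,True,-4.7,
globus_pallidus,T1,without_invivo,539.6,23.2,1.8,1.6,0.32,0.013,False,,-9.8
globus_pallidus,T2,with_invivo,80.7,6.5,-0.1,0.3,-0.01,0.379,False,1.5,
globus_pallidus,T2,without_invivo,80.4,10.5,-0.1,0.8,-0.07,0.786,False,,4.5
globus_pallidus,T2star,with_invivo,16.6,3.4,0.4,0.2,0.64,0.001,True,-32.6,
globus_pallidus,T2star,without_invivo,21.0,4.3,0.1,0.3,-0.03,0.477,False,,-8.6
globus_pallidus,MD,with_invivo,3.9e-05,5.5e-05,1.1e-05,2.4e-06,0.80,0.001,True,-51.5,
globus_pallidus,MD,without_invivo,1.3e-04,5.8e-05,2.5e-06,4.2e-06,0.13,0.093,False,,-36.4
globus_pallidus,FA,with_invivo,5.0e-01,3.6e-02,-2.17e-03,1.7e-03,0.22,0.021,False,12.0,
globus_pallidus,FA,without_invivo,4.8e-01,3.9e-02,-7.1e-04,2.8e-03,-0.06,0.740,False,,5.1
putamen,T1,with_invivo,464.8,25.9,9.2,1.2,0.94,0.001,True,-9.7,
putamen,T1,without_invivo,500.6,33.4,6.5,2.1,0.76,0.001,True,,-28.6
putamen,T2,with_invivo,76.6,6.0,0.0,0.4,-0.05,0.914,False,-1.2,
putamen,T2,without_invivo,76.7,9.9,0.0,0.8,-0.05,0.569,False,,1.0
putamen,T2star,with_invivo,18.4,4.1,0.5,0.2,0.53,0.001,True,-26.7,
putamen,T2star,without_invivo,22.2,6.0,0.15,0.44,-0.04,0.548,False,,-17.3
putamen,MD,with_invivo,4.3e-06,3.8e-05,1.5e-05,1.7e-06,0.86,0.001,True,-50.0,
putamen,MD,without_invivo,1.2e-04,5.2e-05,5.1e-06,3.7e-06,0.43,0.003,False,,-54.1
putamen,FA,with_invivo,4.7e-01,5.5e-02,-5.6e-03,2.8e-03,0.53,0.001,True,85.2,
putamen,FA,without_invivo,4.0e-01,3.4e-02,6.2e-05,6.4e-04,0.00,0.868,False,,-0.5
caudate_nucleus,T1,with_invivo,535.7,50.8,5.8,2.2,0.69,0.001,True,-1.0,
caudate_nucleus,T1,without_invivo,539.1,86.4,5.6,5.4,0.29,0.018,False,,-24.4
caudate_nucleus,T2,with_invivo,91.8,4.7,-0.3,0.3,0.29,0.008,False,-4.2,
caudate_nucleus,T2,without_invivo,93.1,7.7,-0.4,0.6,0.13,0.095,False,,17.4
caudate_nucleus,T2star,with_invivo,25.8,4.1,0.5,0.2,0.52,0.001,True,-26.1,
caudate_nucleus,T2star,without_invivo,30.0,5.9,0.08,0.44,-0.06,0.663,False,,-8.0
caudate_nucleus,MD,with_invivo,-1.5e-05,8.3e-05,1.7e-05,4.2e-06,0.85,0.001,True,-51.8,
caudate_nucleus,MD,without_invivo,1.3e-04,6.3e-05,5.0e-06,4.3e-06,0.34,0.011,False,,-52.4
caudate_nucleus,FA,with_invivo,4.6e-01,6.0e-02,-4.2e-03,3.1e-03,0.37,0.003,False,54.9,
caudate_nucleus,FA,without_invivo,4.1e-01,4.0e-02,1.3e-04,1.7e-03,-0.07,0.825,False,,-1.0
thalamus,T1,with_invivo,566.0,52.4,4.4,2.4,0.54,0.001,True,-5.6,
thalamus,T1,without_invivo,584.7,90.5,3.0,6.0,0.10,0.119,False,,-13.9
thalamus,T2,with_invivo,101.6,6.3,-0.4,0.3,0.17,0.039,False,3.9,
thalamus,T2,without_invivo,100.2,10.9,-0.2,0.8,-0.01,0.373,False,,8.1
thalamus,T2star,with_invivo,25.7,3.2,0.4,0.1,0.61,0.001,True,-21.8,
thalamus,T2star,without_invivo,29.3,4.5,0.11,0.33,-0.03,0.444,False,,-10.5
thalamus,MD,with_invivo,-4.0e-06,5.5e-05,1.7e-05,4.1e-06,0.86,0.001,True,-47.9,
thalamus,MD,without_invivo,1.3e-04,5.5e-05,5.8e-06,3.8e-06,0.38,0.007,False,,-55.4
thalamus,FA,with_invivo,4.0e-01,5.0e-02,-1.1e-03,2.5e-03,0.02,0.264,False,53.3,
thalamus,FA,without_invivo,3.4e-01,6.8e-02,4.0e-03,4.7e-03,0.09,0.132,False,,-26.5
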