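patient_id,prescription_dose,n_fractions,site,n_arcs,n_noncoplanar,pi_percent,d98,d50,d2,v_ptv,v_piv,v_overlap,hi_published,ci_published
1,25,5,Abdomen,2,0,98,24.4,25.0,25.6,37.7,39.20,35.30,0.05,1.19
2,48,8,Thorax,2,0,99,33.4,46.5,48.7,59.8,42.01,34.50,0.33,2.11
3,50,5,Thorax,2,0,97,47.9,50.1,51.5,84.2,84.05,79.10,0.07,1.13
4,24,3,Thorax,2,0,96,14.3,23.9,24.9,135.3,129.71,109.70,0.44,1.46
5,40,5,Thorax,2,0,97,38.8,40.3,41.5,54.3,58.13,51.20,0.07,1.20
6,35,5,Abdomen,2,0,98,34.2,35.0,35.7,44.0,43.85,39.00,0.04,1.27
7,30,5,Abdomen,2,0,98,29.4,30.0,30.7,62.1,62.10,57.40,0.04,1.17
8,30,3,Pelvis,2,0,98,29.2,30.0,30.7,26.9,27.64,25.20,0.05,1.17
9,50,5,Thorax,2,0,97,48.6,50.0,51.3,17.7,18.62,16.60,0.05,1.20
10,40,5,Thorax,2,0,97,38.5,40.4,41.4,63.3,62.82,58.40,0.07,1.17
11,27,1,Head-Neck,3,2,87,27.8,26.7,31.1,2.8,5.35,2.80,0.12,1.91
12,27,1,Head-Neck,4,3,96,26.0,26.7,28.1,1.3,1.51,1.10,0.08,1.62
13,27,1,Head-Neck,3,2,96,24.5,27.8,28.2,0.5,0.40,0.30,0.13,2.22
14,40,5,Head-Neck,2,0,98,39.3,40.0,40.8,10.3,11.10,10.00,0.04,1.14
15,40,5,Head-Neck,2,0,98,39.5,40.0,40.8,7.3,7.16,6.80,0.03,1.13
16,25,5,Head-Neck,2,0,97,23.3,25.1,25.9,8.1,7.86,7.10,0.10,1.26
17,20,5,Head-Neck,2,0,95,18.9,20.0,21.0,10.4,12.48,10.00,0.11,1.30
18,27,1,Head-Neck,3,1,98,24.5,26.9,27.6,2.3,1.45,1.30,0.11,1.97
19,45,3,Thorax,2,0,94,43.7,45.6,47.6,7.0,9.05,7.00,0.09,1.29
20,50,5,Thorax,2,0,97,48.4,50.0,51.4,11.2,12.20,10.30,0.06,1.29
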