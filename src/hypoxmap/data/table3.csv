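patient,fdg_suv_max,mtv_cm3,tlg,fmiso_suv_max,hsv_fdg_cm3,hsv_mri_cm3,hsv_union_cm3,mri_volume_cm3
1,8.4,2.2,10.78,2.64,0.0,0.0,0.0,2.63
2,15.4,71.54,676.77,2.08,2.03,2.25,2.25,162.89
3,10.43,13.42,77.43,2.51,0.86,1.22,1.22,29.1
4,13.32,7.82,66.08,2.24,1.2,1.76,2.22,10.92
5,14.67,18.75,204.19,2.46,2.59,4.3,4.84,49.96
6,10.87,11.86,92.98,2.12,0.2,0.2,0.46,10.48
7,10.86,17.29,135.21,1.75,0.17,0.83,0.83,59.19
8,11.32,4.4,26.62,2.79,0.66,1.71,2.98,7.01
9,8.69,9.76,47.43,1.25,0.0,0.0,0.0,30.51
10,11.14,31.59,219.87,2.44,4.35,4.13,5.82,62.22
11,7.81,1.8,8.17,1.92,0.0,0.0,0.0,1.33
12,5.74,12.22,48.02,2.3,0.4,0.0,0.51,6.72
13,14.18,20.12,179.47,3.56,5.75,21.49,26.16,93.59
14,9.52,7.09,38.71,1.84,0.37,0.76,0.76,15.49
15,34.9,12.23,237.87,3.26,4.01,3.55,4.91,21.8
16,9.25,2.01,15.74,2.28,0.15,0.0,0.15,1.76
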