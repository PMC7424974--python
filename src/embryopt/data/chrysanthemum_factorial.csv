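d24_uM,kin_uM,snp_uM,cal_mean,cal_se,emb_mean,emb_se,num_mean,num_se
0,0,0,0.00,0.00,0.00,0.00,0.00,0.00
4.54,0,0,84.44,5.56,0.00,0.00,0.00,0.00
9.09,0,0,93.33,3.33,0.00,0.00,0.00,0.00
13.63,0,0,100.00,0.00,0.00,0.00,0.00,0.00
0,4.65,0,0.00,0.00,0.00,0.00,0.00,0.00
4.54,4.65,0,80.00,4.71,48.89,5.88,4.48,0.34
9.09,4.65,0,100.00,0.00,100.00,0.00,31.71,0.74
13.63,4.65,0,100.00,0.00,71.11,5.88,9.02,0.34
0,9.29,0,22.22,7.78,0.00,0.00,0.00,0.00
4.54,9.29,0,91.11,4.84,73.33,5.77,7.69,0.24
9.09,9.29,0,100.00,0.00,100.00,0.00,21.73,0.44
13.63,9.29,0,100.00,0.00,100.00,0.00,4.23,0.30
0,13.94,0,24.44,8.01,0.00,0.00,0.00,0.00
4.54,13.94,0,97.78,2.22,60.00,6.67,6.93,0.24
9.09,13.94,0,100.00,0.00,86.67,4.71,13.01,0.36
13.63,13.94,0,100.00,0.00,100.00,0.00,4.06,0.24
0,0,10,0.00,0.00,0.00,0.00,0.00,0.00
4.54,0,10,88.89,4.84,0.00,0.00,0.00,0.00
9.09,0,10,95.56,2.94,0.00,0.00,0.00,0.00
13.63,0,10,100.00,0.00,0.00,0.00,0.00,0.00
0,4.65,10,0.00,0.00,0.00,0.00,0.00,0.00
4.54,4.65,10,91.11,4.84,62.22,7.03,5.96,0.39
9.09,4.65,10,100.00,0.00,100.00,0.00,35.60,0.69
13.63,4.65,10,100.00,0.00,86.67,4.71,9.87,0.36
0,9.29,10,31.11,6.76,0.00,0.00,0.00,0.00
4.54,9.29,10,95.56,4.44,86.67,4.71,8.82,0.29
9.09,9.29,10,100.00,0.00,100.00,0.00,25.86,0.63
13.63,9.29,10,100.00,0.00,100.00,0.00,5.51,0.26
0,13.94,10,33.33,7.45,0.00,0.00,0.00,0.00
4.54,13.94,10,100.00,0.00,75.56,4.44,7.77,0.20
9.09,13.94,10,100.00,0.00,100.00,0.00,16.79,0.37
13.63,13.94,10,100.00,0.00,100.00,0.00,5.28,0.19
0,0,20,0.00,0.00,0.00,0.00,0.00,0.00
4.54,0,20,95.56,2.94,2.22,2.22,0.22,0.22
9.09,0,20,100.00,0.00,4.44,2.94,0.33,0.24
13.63,0,20,100.00,0.00,0.00,0.00,0.00,0.00
0,4.65,20,13.33,7.45,8.89,4.84,0.73,0.37
4.54,4.65,20,100.00,0.00,84.44,5.56,9.56,0.21
9.09,4.65,20,100.00,0.00,100.00,0.00,57.80,0.21
13.63,4.65,20,100.00,0.00,100.00,0.00,17.07,0.29
0,9.29,20,46.67,5.77,13.33,4.71,0.81,0.30
4.54,9.29,20,100.00,0.00,100.00,0.00,11.64,0.19
9.09,9.29,20,100.00,0.00,100.00,0.00,29.08,0.26
13.63,9.29,20,100.00,0.00,100.00,0.00,7.38,0.20
0,13.94,20,57.78,7.03,17.78,5.21,0.78,0.22
4.54,13.94,20,100.00,0.00,95.56,2.94,11.38,0.26
9.09,13.94,20,100.00,0.00,100.00,0.00,25.63,0.42
13.63,13.94,20,100.00,0.00,100.00,0.00,8.60,0.34
0,0,40,0.00,0.00,0.00,0.00,0.00,0.00
4.54,0,40,97.78,2.22,0.00,0.00,0.00,0.00
9.09,0,40,100.00,0.00,2.22,2.22,0.22,0.22
13.63,0,40,100.00,0.00,0.00,0.00,0.00,0.00
0,4.65,40,17.78,6.19,8.89,3.51,0.44,0.18
4.54,4.65,40,100.00,0.00,77.78,5.21,8.06,0.13
9.09,4.65,40,100.00,0.00,100.00,0.00,45.77,0.33
13.63,4.65,40,100.00,0.00,100.00,0.00,14.54,0.20
0,9.29,40,31.11,4.84,11.11,4.84,0.44,0.18
4.54,9.29,40,100.00,0.00,100.00,0.00,8.83,0.18
9.09,9.29,40,100.00,0.00,100.00,0.00,24.74,0.18
13.63,9.29,40,100.00,0.00,100.00,0.00,6.58,0.17
0,13.94,40,68.89,5.88,11.11,3.51,0.56,0.18
4.54,13.94,40,100.00,0.00,93.33,3.33,10.60,0.14
9.09,13.94,40,100.00,0.00,100.00,0.00,21.32,0.28
13.63,13.94,40,100.00,0.00,91.11,3.51,7.59,0.18
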