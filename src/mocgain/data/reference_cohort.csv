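subject_id,G_max,c,BP_ctr,k,mu,P,dG,c_tilde
S1,17.80,0.43,42.68,1.34,0.61,25.69,4.04,0.56
S2,25.92,0.15,44.11,2.06,0.40,29.48,-0.98,0.12
S3,27.69,0.07,41.00,1.42,0.12,20.70,-0.60,0.05
S4,29.41,0.18,50.07,2.08,0.54,14.74,3.74,0.29
S5,13.08,0.17,37.88,2.60,0.71,34.33,1.39,0.26
S6,35.39,0.19,52.74,0.69,0.54,12.26,4.43,0.29
S7,13.50,0.56,38.50,1.42,0.77,33.19,13.50,1.00
S8,23.28,0.15,42.93,1.27,0.21,17.29,-0.71,0.13
S9,27.11,0.15,52.65,1.58,0.39,11.01,1.18,0.19
S10,26.75,0.07,42.79,1.32,0.13,13.75,0.87,0.10
S11,23.99,0.38,48.77,1.70,0.56,22.59,4.18,0.49
S12,22.21,0.65,48.31,3.00,0.97,20.66,22.21,1.00
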