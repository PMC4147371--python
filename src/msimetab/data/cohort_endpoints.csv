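subject_id,age,bmi,pct_fat,vo2max,d_vo2max,wmax,d_wmax,fg,d_fg,p2hg,d_p2hg,tauc,d_tauc
S1,24,25.5,33.8,39.3,-0.90,248,18,3.8,1.1,4.8,0.17,713,85.8
S2,25,26.3,40.0,31.1,4.4,195,30,5.1,0.88,5.1,3.20,813,443
S3,23,25.7,31.7,26.8,9.2,266,20,5.0,-0.33,4.1,-0.54,631,-83.1
S4,41,27.8,40.1,29.3,3.1,205,41,5.0,-0.27,5.5,-0.88,734,-43.1
S5,23,27.4,47.1,29.8,11,173,54,4.2,0.09,5.9,-0.88,784,-117
S6,33,25.6,35.1,33.9,4.8,228,17,5.4,-1.80,4.2,0.86,507,-0.77
S7,41,36.1,50.1,19.4,3.0,190,40,5.1,-1.00,5.2,-1.10,628,-71.5
S8,21,25.1,37.1,30.4,7.6,194,12,4.2,-0.17,4.9,-1.20,702,-34.2
S9,22,27.5,46.6,33.5,1.1,200,0,4.0,0.68,7.5,-0.71,950,-93.9
S10,20,32.8,48.2,21.2,3.8,166,20,6.2,-1.50,6.3,0.09,931,-144
S11,23,30.0,50.5,24.1,5.3,170,30,4.0,-0.28,4.2,0.39,656,-33.6
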