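diameter_deg,distance,direction,M_data,N_trials
7.5,2.5,horizontal,0.44,68
7.5,2.5,vertical,0.44,68
11.25,2.5,horizontal,0.72,68
11.25,2.5,vertical,0.72,68
16.88,2.5,horizontal,0.60,68
16.88,2.5,vertical,0.60,68
25.31,2.5,horizontal,0.32,68
25.31,2.5,vertical,0.32,68
38.0,2.5,horizontal,0.00,68
38.0,2.5,vertical,0.00,68
7.5,3.75,horizontal,0.06,68
7.5,3.75,vertical,0.06,68
11.25,3.75,horizontal,0.15,68
11.25,3.75,vertical,0.15,68
16.88,3.75,horizontal,0.26,68
16.88,3.75,vertical,0.26,68
25.31,3.75,horizontal,0.24,68
25.31,3.75,vertical,0.24,68
38.0,3.75,horizontal,0.00,68
38.0,3.75,vertical,0.00,68
7.5,5.63,horizontal,0.00,68
7.5,5.63,vertical,0.00,68
11.25,5.63,horizontal,0.02,68
11.25,5.63,vertical,0.02,68
16.88,5.63,horizontal,0.00,68
16.88,5.63,vertical,0.00,68
25.31,5.63,horizontal,0.03,68
25.31,5.63,vertical,0.03,68
38.0,5.63,horizontal,0.00,68
38.0,5.63,vertical,0.00,68
7.5,10.0,horizontal,0.00,68
7.5,10.0,vertical,0.00,68
11.25,10.0,horizontal,0.00,68
11.25,10.0,vertical,0.00,68
16.88,10.0,horizontal,0.00,68
16.88,10.0,vertical,0.00,68
25.31,10.0,horizontal,0.00,68
25.31,10.0,vertical,0.00,68
38.0,10.0,horizontal,0.00,68
38.0,10.0,vertical,0.00,68
7.5,monocular,horizontal,0.00,68
7.5,monocular,vertical,0.00,68
11.25,monocular,horizontal,0.00,68
11.25,monocular,vertical,0.00,68
16.88,monocular,horizontal,0.00,68
16.88,monocular,vertical,0.00,68
25.31,monocular,horizontal,0.00,68
25.31,monocular,vertical,0.00,68
38.0,monocular,horizontal,0.00,68
38.0,monocular,vertical,0.00,68
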