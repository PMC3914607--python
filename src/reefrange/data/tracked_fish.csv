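species,fish_id,total_length_cm,peripheral,days,asymptote,mcp_km2,kd_km2,detections,pct_total_detections,moves,pct_total_moves
RG,36,64,Moderate,18,No,8.16,12.21,2198,0.1,300,1.8
RG,37,47,Low,179,Yes,0.47,0.10,64672,3.1,85,0.5
RG,41,47,Low,179,Yes,0.44,0.09,75732,3.6,61,0.4
RG,42,48,Low,179,Yes,0.93,0.07,21823,1.1,484,2.9
RG,47,48,Moderate,11,No,12.3,17.16,1534,0.1,57,0.3
RG,51,66,Low,157,Yes,1.95,0.17,12329,0.6,1149,6.8
RG,170,61,High,93,No,Linear,Linear,705,0.0,11,0.1
RG,171,60,High,98,Yes,0.64,4.89,2359,0.1,23,0.1
RG,172,49,High,3,No,5.14,7.39,471,0.0,29,0.2
RG,173,49,Moderate,92,Yes,1.28,4.44,611,0.0,116,0.7
RG,175,53,Moderate,96,No,Linear,Linear,5190,0.3,8,0.0
RG,176,55,High,93,Yes,0.64,3.21,4512,0.2,32,0.2
RG,177,50,High,89,No,Linear,Linear,373,0.0,6,0.0
RG,178,65,High,90,No,Linear,Linear,2591,0.1,193,1.1
RG,179,57,Moderate,23,Maybe,7.39,19.90,244,0.0,36,0.2
RG,180,55,Moderate,40,Maybe,3.19,12.17,380,0.0,93,0.6
RG,181,49,High,13,Maybe,1.97,4.07,883,0.0,38,0.2
RG,183,48,High,98,Yes,3.22,0.01,8491,0.4,1325,7.9
RG,184,55,Low,43,Yes,1.91,1.06,4915,0.2,848,5.0
RG,185,55,Low,43,Yes,1.9,0.66,8895,0.4,171,1.0
RG,186,51,Moderate,91,Yes,3.49,0.55,12327,0.6,1259,7.5
RG,187,50,Low,92,Yes,1.89,1.31,4806,0.2,965,5.7
RG,190,62,High,101,Yes,Linear,Linear,55093,2.7,25,0.1
RG,191,51,High,93,Yes,0.63,0.85,36329,1.8,38,0.2
RG,194,54,High,94,Maybe,1.55,0.88,12928,0.6,106,0.6
RG,862,54,Very high,86,Maybe,0.92,1.00,73728,3.6,26,0.2
RG,863,51,High,95,Yes,0.31,5.32,6728,0.3,7,0.0
RG,864,55,High,92,No,Linear,Linear,44890,2.2,892,5.3
RG,865,56,High,33,Yes,1.28,0.39,14616,0.7,1027,6.1
RG,866,53,High,66,No,Linear,Linear,424,0.0,73,0.4
RG,867,55,High,89,Yes,0.49,0.12,42058,2.0,2687,16.0
RG,868,49,High,88,No,Linear,Linear,24533,1.2,489,2.9
RG,869,60,High,87,No,Linear,Linear,21703,1.0,2978,17.7
RG,870,45,High,25,Yes,2.2,2.25,2528,0.1,354,2.1
RG,871,57,High,76,No,Linear,Linear,400,0.0,103,0.6
RG,872,53,High,79,Yes,0.49,0.19,70316,3.4,77,0.5
RG,873,48,Low,280,Yes,6.44,0.01,199933,9.6,5,0.0
RG,874,60,Low,278,Yes,1.4,0.12,313240,15.0,173,1.0
RG,875,52,Low,280,Yes,1.68,0.69,205442,9.9,29,0.2
RG,877,57,Low,280,Yes,0.83,0.33,124104,6.0,93,0.6
RG,878,48,Moderate,44,Yes,5.76,2.96,21144,1.0,201,1.2
RG,880,49,Low,269,Yes,2.59,4.38,35437,1.7,14,0.1
RG,881,50,Low,280,Yes,9.17,1.64,261025,12.6,27,0.2
RG,884,53,Low,280,Yes,1.68,0.25,272798,13.1,108,0.6
BG,43,75,Low,179,Yes,2.48,0.12,72644,86.4,410,93.8
BG,174,50,High,91,Yes,0.39,0.35,11466,13.6,27,6.2
MS,50,43,High,4,No,0.19,0.23,183,0.8,39,3.1
MS,53,70,Moderate,168,Yes,7.64,0.58,21825,99.2,1228,96.9
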