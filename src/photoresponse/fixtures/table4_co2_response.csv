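Repeat,CO2S,Photo,Fitted,Trmmol,Tleaf,PARi,Cond,Ci
1,2563.5,5.3565,5.834,1.043,28.09,1000.9,0.0488,2104.6
1,1899.2,9.3139,8.553,0.894,28.13,1001.3,0.0411,1473.1
1,1695.6,9.6047,8.781,0.923,28.14,1001.3,0.0426,1277.7
1,1398.7,7.8518,8.603,0.971,28.24,1001.2,0.0445,1068.9
1,1099.0,7.5999,7.808,1.012,28.07,1001.0,0.0474,825.9
1,999.8,7.2034,7.409,1.012,28.18,1000.8,0.0468,720.1
1,800.2,6.1402,6.401,1.038,28.24,1000.8,0.0478,567.8
1,600.3,5.3804,5.117,1.020,28.06,1001.0,0.0479,400.5
1,400.5,3.4728,3.558,0.966,28.17,1000.6,0.0447,262.8
1,311.7,2.3457,2.777,0.908,28.13,1000.5,0.0420,212.2
1,139.4,1.5264,1.106,0.325,29.06,1199.8,0.0112,80.5
1,91.2,0.7625,0.602,0.856,29.55,1200.6,0.0185,20.9
2,2567.3,7.3494,7.740,0.741,28.10,1000.4,0.0345,1987.4
2,1897.3,9.4502,9.061,0.667,28.11,1000.1,0.0309,1295.6
2,1696.8,9.7506,8.980,0.682,28.11,1000.3,0.0316,1149.0
2,1398.4,8.3402,8.453,0.690,28.09,1000.2,0.0321,937.5
2,1099.3,7.4384,7.435,0.733,28.10,1000.3,0.0341,715.3
2,1000.5,6.8615,6.991,0.712,28.09,1000.2,0.0332,637.9
2,800.4,5.6185,5.929,0.720,28.09,1000.3,0.0336,507.4
2,601.4,4.2436,4.654,0.697,28.09,1000.2,0.0325,373.7
2,399.8,2.7830,3.142,0.641,28.08,1000.1,0.0298,238.1
2,310.1,2.2032,2.397,1.014,28.22,1000.6,0.0468,224.3
2,113.4,1.4361,0.610,0.322,28.00,1200.3,0.0111,95.2
2,88.8,0.3868,0.371,0.920,27.89,1200.9,0.0561,75.4
3,2564.2,6.6075,7.192,0.696,28.08,1000.3,0.0342,2016.5
3,1898.3,8.6724,8.913,0.609,28.09,1000.7,0.0477,1352.5
3,1696.5,9.6606,8.917,0.585,28.09,1000.1,0.0325,1077.5
3,1399.2,8.1282,8.482,0.698,28.10,1000.3,0.0324,952.8
3,1099.7,7.3780,7.513,0.705,28.14,999.9,0.0303,805.4
3,999.7,6.6075,7.071,0.676,28.04,1000.2,0.0388,685.7
3,800.3,6.0660,6.012,1.040,28.17,1001.1,0.0483,572.3
3,600.4,4.7405,4.714,1.028,28.18,1000.7,0.0476,421.0
3,413.5,3.2650,3.285,1.003,28.14,1000.9,0.0466,287.5
3,311.0,2.1327,2.413,0.974,28.14,1001.0,0.0452,225.0
3,202.1,1.0168,1.418,0.866,28.13,1199.8,0.0340,146.6
3,105.2,0.6105,0.473,0.750,28.03,1200.5,0.0199,51.2
3,83.9,0.0484,0.323,0.992,28.75,1200.8,0.0324,77.5
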