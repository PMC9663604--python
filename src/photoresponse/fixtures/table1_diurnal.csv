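Repeat,Time,Photo,PARi,Tleaf,CO2S,Trmmol,Cond,Ci
1,7:12,0.0780,108.5,28.68,433.0,0.0433,0.000578,372.1
1,8:01,0.0931,176.8,31.67,433.0,0.0435,0.000153,371.0
1,9:01,0.1888,628.7,33.24,433.1,0.0433,0.000578,201.7
1,10:13,0.1070,1460.9,33.53,434.1,0.1344,0.001138,221.6
1,11:04,0.0615,1578.3,35.16,427.0,0.1593,0.000865,218.2
1,12:00,0.0377,1667.6,36.44,425.4,0.2048,0.001061,262.4
1,13:15,0.0053,1598.9,37.25,421.2,0.2590,0.001659,323.1
1,14:04,0.0276,1554.4,37.27,416.9,0.1860,0.001404,308.5
1,15:00,0.0140,1446.8,36.39,415.3,0.0977,0.000652,295.7
1,16:00,0.0752,1163.1,35.08,413.2,0.0487,0.000439,94.0
1,17:00,0.1485,934.4,34.01,411.8,0.0586,0.000708,45.7
1,18:00,0.1017,544.7,33.16,412.4,0.0353,0.000545,88.2
1,19:00,0.0678,58.3,32.28,415.0,0.0367,0.000734,241.0
2,7:12,0.0813,100.6,28.64,433.1,0.0415,0.000558,386.0
2,8:01,0.1014,180.7,31.65,433.0,0.0492,0.000223,373.3
2,9:01,0.2082,589.5,33.26,433.0,0.0469,0.000596,171.4
2,10:13,0.1086,1432.3,33.47,435.1,0.1358,0.000909,171.4
2,11:04,0.0642,1578.4,35.17,427.0,0.1590,0.000864,213.7
2,12:00,0.0400,1668.4,36.45,425.5,0.2057,0.001063,259.1
2,13:15,0.0089,1555.1,37.23,421.0,0.2527,0.002035,338.5
2,14:04,0.0376,1554.3,37.27,416.9,0.1857,0.001434,300.6
2,15:00,0.0185,1349.0,36.51,414.5,0.0965,0.000773,304.4
2,16:00,0.0779,1153.2,35.08,413.1,0.0512,0.000456,94.5
2,17:00,0.1552,933.5,34.01,411.8,0.0599,0.000735,44.2
2,18:00,0.1037,543.9,33.15,412.4,0.0356,0.000549,84.3
2,19:00,0.0691,58.4,32.27,415.0,0.0363,0.000728,236.8
3,7:12,0.0855,105.5,28.56,433.3,0.0363,0.000532,386.1
3,8:01,0.1086,178.8,31.65,433.0,0.0363,0.000202,371.2
3,9:01,0.2234,591.9,33.26,433.0,0.0437,0.000556,220.4
3,10:13,0.1122,1460.8,33.53,434.0,0.1333,0.001142,216.0
3,11:04,0.0689,1634.3,35.59,425.6,0.1294,0.000783,201.7
3,12:00,0.0488,1667.9,36.44,425.4,0.2057,0.001064,247.9
3,13:15,0.0093,1598.9,37.25,421.2,0.2595,0.00165,319.0
3,14:04,0.0432,1530.9,37.07,417.4,0.2176,0.001347,276.4
3,15:00,0.0228,1397.9,36.32,414.8,0.0999,0.000889,308.7
3,16:00,0.0859,1147.0,35.09,413.2,0.0517,0.000458,69.4
3,17:00,0.1679,934.3,34.01,411.8,0.0584,0.00071,16.2
3,18:00,0.1051,571.0,33.71,412.5,0.0390,0.000498,46.1
3,19:00,0.0706,58.4,32.26,415.0,0.0368,0.000738,236.0
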