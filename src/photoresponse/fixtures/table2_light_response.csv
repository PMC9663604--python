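Repeat,PARi,Photo,Fitted,CO2S,Trmmol,Tleaf,Cond,Ci
1,2000.5,2.005,1.897,400.3,0.670,28.07,0.0496,326.6
1,1800.1,2.108,2.050,399.6,0.623,28.09,0.0450,315.6
1,1498.9,2.147,2.272,400.2,0.640,27.93,0.0311,277.4
1,1399.9,2.177,2.342,400.1,0.539,28.10,0.0380,299.3
1,1001.2,2.684,2.600,399.5,0.491,28.12,0.0340,264.1
1,801.5,2.705,2.702,400.2,0.454,27.96,0.0369,245.4
1,600.8,2.736,2.765,399.8,0.442,28.14,0.0301,245.2
1,399.6,2.699,2.738,400.3,0.416,28.14,0.0280,242.6
1,199.7,2.570,2.419,399.8,0.396,28.14,0.0264,235.2
1,150.8,2.250,2.205,399.3,0.405,28.14,0.0268,238.1
1,100.6,1.825,1.833,400.1,0.387,28.15,0.0254,276.1
1,49.6,0.925,1.092,399.9,0.400,28.15,0.0261,333.7
1,20.5,0.341,0.266,400.7,0.373,28.15,0.0242,368.4
2,2000.1,2.171,2.077,400.1,0.809,28.09,0.0543,326.2
2,1800.1,2.374,2.350,400.0,0.719,28.11,0.0477,297.1
2,1499.9,2.720,2.713,399.6,0.678,28.12,0.0448,274.9
2,1199.1,2.777,2.991,400.0,0.626,28.13,0.0411,284.3
2,999.3,3.008,3.102,399.7,0.560,28.14,0.0364,257.9
2,799.8,3.213,3.120,400.5,0.531,28.15,0.0345,280.7
2,601.0,3.073,2.995,400.4,0.486,28.16,0.0314,255.4
2,399.7,2.688,2.617,399.5,0.462,28.16,0.0299,267.7
2,199.7,1.904,1.753,399.8,0.414,28.15,0.0269,277.0
2,149.8,1.241,1.404,400.8,0.230,27.97,0.0072,330.0
2,100.7,0.837,0.978,400.3,0.246,28.05,0.0117,334.3
2,49.8,0.338,0.425,399.9,0.256,27.97,0.0123,285.6
2,20.5,0.156,0.040,399.4,0.281,28.06,0.0133,335.2
3,1999.9,0.952,0.898,484.7,0.944,28.79,0.0113,297.0
3,1800.6,1.226,1.201,483.3,0.964,28.20,0.0135,293.4
3,1599.8,1.423,1.497,480.8,0.955,28.35,0.0158,298.1
3,1400.8,1.751,1.779,477.7,0.925,27.84,0.0179,288.3
3,1200.6,2.004,2.046,474.3,0.892,28.51,0.0202,287.0
3,1001.2,2.230,2.286,471.3,0.822,28.29,0.0217,282.7
3,800.5,2.570,2.485,468.6,0.751,28.13,0.0233,285.1
3,600.7,2.676,2.607,465.8,0.678,28.01,0.0249,288.0
3,399.7,2.493,2.571,463.7,0.713,28.24,0.0301,305.6
3,200.2,2.164,2.109,463.1,0.779,27.87,0.0330,341.7
3,149.6,1.823,1.825,462.3,0.793,27.55,0.0317,353.1
3,99.5,1.420,1.398,461.4,0.751,28.16,0.0299,367.9
3,49.7,0.617,0.725,461.2,0.702,28.26,0.0286,409.2
3,20.8,0.195,0.136,458.8,0.523,28.11,0.0194,423.4
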