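Repeat,PAR,Y(II),Y(NPQ),Y(NO),NPQ,qN,qP,qL,ETR,Fitted
1,0,0.573,0,0.427,0,0,1,1,0,0
1,6,0.36,0.264,0.376,0.701,0.559,0.837,0.745,0.9,0.503
1,31,0.184,0.529,0.287,1.846,0.831,0.667,0.592,2.4,2.273
1,101,0.124,0.585,0.292,2.005,0.843,0.459,0.383,5.3,5.502
1,198,0.098,0.604,0.298,2.027,0.849,0.374,0.306,8.1,7.988
1,363,0.066,0.626,0.308,2.034,0.856,0.265,0.213,10.1,10.244
1,619,0.049,0.637,0.314,2.027,0.849,0.187,0.145,12.7,12.079
1,981,0.032,0.648,0.32,2.027,0.853,0.125,0.096,13.1,13.603
1,1386,0.02,0.657,0.323,2.034,0.856,0.078,0.06,14.4,14.839
1,2015,0.015,0.664,0.321,2.064,0.856,0.059,0.045,16.6,16.497
1,2970,0.015,0.665,0.32,2.08,0.862,0.061,0.047,18.6,19.070
1,3588,0.015,0.666,0.319,2.087,0.858,0.059,0.045,22.5,20.978
1,4292,0.013,0.672,0.315,2.134,0.873,0.056,0.043,22.8,23.547
2,0,0.562,0,0.438,0,0,1,1,0,0.00
2,6,0.325,0.268,0.407,0.659,0.555,0.783,0.679,0.8,0.279
2,31,0.165,0.544,0.291,1.87,0.849,0.68,0.617,2.2,1.371
2,101,0.111,0.602,0.286,2.103,0.869,0.488,0.424,4.7,3.914
2,198,0.087,0.62,0.293,2.111,0.869,0.381,0.322,7.2,6.554
2,363,0.063,0.639,0.298,2.146,0.868,0.271,0.221,9.6,9.638
2,619,0.044,0.653,0.303,2.154,0.877,0.203,0.166,11.5,12.601
2,981,0.033,0.661,0.306,2.163,0.871,0.145,0.115,13.7,15.066
2,1386,0.03,0.664,0.306,2.172,0.871,0.133,0.105,17.7,16.760
2,2015,0.019,0.673,0.307,2.189,0.88,0.091,0.073,18.5,18.422
2,2970,0.017,0.677,0.306,2.216,0.883,0.08,0.064,21,20.011
2,3588,0.014,0.681,0.305,2.234,0.883,0.067,0.053,21.3,20.772
2,4292,0.011,0.685,0.304,2.253,0.886,0.055,0.044,20.5,21.510
3,0,0.538,0,0.462,0,0,1,1,0,0.00
3,6,0.376,0.154,0.47,0.327,0.342,0.801,0.681,0.9,0.579
3,31,0.209,0.466,0.325,1.433,0.775,0.709,0.633,2.7,2.621
3,101,0.139,0.553,0.308,1.792,0.837,0.565,0.495,5.9,6.348
3,198,0.106,0.58,0.314,1.85,0.84,0.434,0.366,8.8,9.204
3,363,0.083,0.595,0.322,1.85,0.838,0.333,0.273,12.6,11.756
3,619,0.057,0.615,0.328,1.875,0.852,0.247,0.202,14.3,13.755
3,981,0.036,0.632,0.332,1.901,0.848,0.152,0.12,14.8,15.296
3,1386,0.039,0.629,0.332,1.892,0.848,0.165,0.131,16.1,16.428
3,2015,0.021,0.643,0.335,1.918,0.863,0.099,0.079,17.9,17.777
3,2970,0.015,0.649,0.335,1.936,0.869,0.074,0.059,19,19.583
3,3588,0.014,0.284,0.702,0.405,0.456,0.078,0.065,21.5,20.764
3,4292,0.012,0.652,0.335,1.945,0.867,0.058,0.046,22,22.196
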