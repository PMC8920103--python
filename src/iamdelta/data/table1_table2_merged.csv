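name,ionization_class,clogkw_mg,clogkw_dd2,explogp,clogp_alogps,clogp_marvin,clogd74,logbb,printed_delta_mg,printed_delta_dd2
"1,1,1-trichloroethane",N,1.063,1.247,2.49,2.45,2.04,,0.40,-0.177,-0.196
"1,2-dimethylbenzene",N,1.400,1.635,3.12,3.16,2.98,,0.37,-0.339,-0.396
"1,4-dimethylbenzene",N,1.421,1.599,3.15,3.15,2.98,,0.31,-0.342,-0.460
"1,7-dimethylxanthine",A,-0.073,-0.001,-0.22,-0.63,0.09,0.09,0.06,0.588,0.798
"1-chloro-2,2,2-trifluoroethane",N,0.811,0.774,,1.82,1.86,,0.08,0.070,-0.080
1-hydroxymidazolam,N,1.839,2.043,,3.09,2.9,,-0.07,0.274,0.217
"2,2-dimethylbutane",N,1.283,1.578,3.82,3.74,2.85,,1.04,-1.010,-1.107
2-methylpentane,N,1.388,1.706,3.21,3.66,2.82,,0.97,-0.422,-0.409
3-methylhexane,N,1.561,1.949,,4.18,3.21,,0.90,-0.249,-0.166
3-methylpentane,N,1.292,1.599,3.60,3.98,2.82,,1.01,-0.827,-0.880
4-hydroxymidazolam,N,1.950,2.191,,3.05,3.35,,-0.30,0.029,-0.055
acetaminophen,N,0.184,0.302,0.91,0.51,1.09,,-0.31,0.195,0.335
acetone,N,-0.247,-0.359,-0.24,-0.29,0.38,,-0.15,0.675,0.748
aminopyrine,N,1.045,1.349,1.00,0.94,1.60,,0.00,0.985,1.298
amobarbital,A,0.899,1.181,2.07,1.87,1.86,1.60,0.04,0.364,0.570
antipyrine,N,0.901,1.139,0.56,1.18,1.61,,-0.10,1.189,1.499
bretazenil,N,2.103,2.447,,3.05,2.29,,-0.09,1.021,1.191
cyclohexane,N,1.476,1.671,3.44,,2.38,,0.92,-0.516,-0.659
cyclopropane,N,0.284,0.105,1.72,1.56,1.19,,0.00,-0.346,-0.618
desmonomethylpromazine,B,2.287,2.703,,4.28,3.68,,0.59,0.104,0.149
didanosine,A,-0.404,-0.294,-1.24,-1.26,-0.50,-1.06,-1.30,1.168,1.579
diethylene glycol divinyl ether,N,-0.127,0.200,0.87,1.26,0.87,,0.11,-0.084,0.270
enflurane,N,1.075,1.203,2.10,2.24,2.42,,0.24,0.144,0.125
ethanol,N,-0.534,-0.683,-0.31,-0.40,-0.22,,-0.16,0.444,0.490
ethyl ether,N,0.162,0.308,0.89,1.12,0.70,,0.00,0.189,0.360
ethylbenzene,N,1.398,1.616,3.15,3.27,2.91,,0.20,-0.365,-0.443
flunitrazepam,N,1.621,1.739,2.06,2.20,2.58,,0.06,0.721,0.698
fluroxene,N,0.570,0.637,,1.70,1.58,,0.13,0.051,0.044
halothane,N,1.165,1.300,2.30,2.50,1.97,,0.35,0.075,0.035
indinavir,BB,2.864,2.745,2.90,3.26,2.39,,-0.74,1.299,0.919
isobutyl alcohol,N,0.045,0.169,0.76,0.60,0.65,,-0.17,0.175,0.342
isoflurane,N,1.074,1.207,2.06,2.30,2.48,,0.42,0.174,0.166
isopropyl alcohol,N,-0.241,-0.243,0.05,0.04,0.19,,-0.15,0.451,0.593
mesoridazine,B,2.640,3.027,3.90,3.83,3.41,,-0.36,0.283,0.267
methoxyflurane,N,0.864,1.070,2.21,2.01,1.91,,0.25,-0.154,-0.111
methyl cyclopentane,N,1.140,1.347,3.37,3.15,2.31,,0.93,-0.797,-0.918
methyl ethyl ketone,N,0.047,0.057,0.29,0.41,1.01,,-0.08,0.549,0.669
mirtazapine,B,1.969,2.287,2.90,,3.38,,0.53,0.404,0.461
m-xylene,N,1.410,1.641,3.20,3.15,2.98,,0.29,-0.392,-0.465
nevirapine,N,1.152,1.332,2.50,1.75,2.19,,0.00,-0.096,-0.120
n-heptane,N,1.791,2.189,,,3.28,,0.81,-0.075,0.008
n-hexane,N,1.545,1.861,,,2.88,,0.80,-0.004,0.054
nordazepam,N,1.838,2.055,,2.79,3.24,,0.50,0.004,-0.088
northioridazine,B,3.120,3.607,,5.29,5.1,,0.75,-0.187,-0.273
n-pentane,N,1.299,1.529,,,2.49,,0.76,0.059,0.086
quinidine,B,2.016,2.394,3.44,2.82,2.32,,-0.46,0.024,0.064
sulforidazine,B,2.684,3.057,4.45,4.32,3.6,,0.18,-0.108,-0.216
teflurane,N,1.029,1.066,,2.07,1.63,,0.27,0.470,0.427
thioridazine,B,3.318,3.816,5.90,5.93,5.48,,0.24,-0.623,-0.812
thioxolone,N,2.414,2.834,3.90,2.69,2.93,,0.40,0.057,0.074
tiotidine,B,0.186,0.375,0.68,0.59,1.18,,-0.82,0.379,0.623
triazolam,N,2.102,2.365,2.42,2.94,3.31,,0.74,0.917,0.988
trichloroethylene,N,0.837,0.944,,2.45,2.17,,0.34,-0.150,-0.200
trifluoperazine,BB,3.305,3.651,5.03,4.87,4.72,,1.44,0.053,-0.164
valproic acid,A,1.135,1.542,2.75,2.54,2.61,0.37,-0.22,1.574,2.079
zidovudine,A,-0.063,0.094,0.05,-0.1,-0.22,-0.28,-0.72,0.891,1.239
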