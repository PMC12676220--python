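province,usdot_both,usdot_male,usdot_female,oecd_both,oecd_male,oecd_female,wage_both,wage_male,wage_female
Aceh,0.339,0.285,0.104,0.230,0.193,0.070,0.182,0.153,0.056
Bali,0.167,0.114,0.073,0.113,0.077,0.050,0.090,0.061,0.039
Bangka-Belitung Islands,0.112,0.086,0.041,0.076,0.058,0.028,0.060,0.046,0.022
Banten,0.856,0.701,0.278,0.580,0.475,0.188,0.459,0.376,0.149
Bengkulu,0.122,0.098,0.042,0.083,0.066,0.028,0.066,0.052,0.022
Central Java,1.383,1.063,0.506,0.938,0.720,0.343,0.742,0.570,0.272
Central Kalimantan,0.203,0.137,0.090,0.137,0.093,0.061,0.109,0.073,0.048
Central Sulawesi,0.299,0.238,0.102,0.202,0.161,0.069,0.160,0.128,0.055
East Java,1.447,1.117,0.525,0.981,0.757,0.356,0.777,0.599,0.282
East Kalimantan,0.186,0.143,0.068,0.126,0.097,0.046,0.100,0.077,0.037
East Nusa Tenggara,0.560,0.396,0.233,0.379,0.269,0.158,0.300,0.213,0.125
Gorontalo,0.143,0.101,0.060,0.097,0.068,0.040,0.077,0.054,0.032
Indonesia,16.130,12.472,5.837,10.936,8.451,3.957,8.658,6.692,3.134
Jakarta,0.330,0.264,0.112,0.224,0.179,0.076,0.177,0.142,0.060
Jambi,0.174,0.133,0.064,0.118,0.090,0.044,0.094,0.071,0.035
Lampung,0.550,0.450,0.178,0.373,0.305,0.121,0.295,0.241,0.096
Maluku,0.204,0.141,0.088,0.139,0.096,0.059,0.110,0.076,0.047
North Kalimantan,0.066,0.052,0.023,0.044,0.035,0.016,0.035,0.028,0.012
North Maluku,0.159,0.120,0.060,0.108,0.081,0.041,0.085,0.064,0.032
North Sulawesi,0.194,0.162,0.060,0.132,0.110,0.041,0.104,0.087,0.032
North Sumatra,1.446,1.183,0.469,0.980,0.802,0.318,0.776,0.635,0.252
Papua,0.696,0.559,0.235,0.472,0.379,0.159,0.374,0.300,0.126
Riau,0.335,0.277,0.107,0.227,0.188,0.072,0.180,0.149,0.057
Riau Islands,0.116,0.109,0.026,0.079,0.074,0.018,0.062,0.058,0.014
South Kalimantan,0.314,0.239,0.118,0.213,0.162,0.080,0.169,0.128,0.063
South Sulawesi,0.584,0.460,0.205,0.396,0.312,0.139,0.313,0.247,0.110
South Sumatra,0.655,0.517,0.228,0.444,0.350,0.155,0.351,0.277,0.122
Southeast Sulawesi,0.320,0.258,0.107,0.217,0.175,0.072,0.172,0.138,0.057
West Java,2.856,2.141,1.089,1.936,1.451,0.738,1.533,1.149,0.584
West Kalimantan,0.281,0.180,0.133,0.191,0.122,0.090,0.151,0.097,0.071
West Nusa Tenggara,0.390,0.286,0.153,0.264,0.194,0.104,0.209,0.154,0.082
West Papua,0.100,0.074,0.039,0.068,0.050,0.026,0.054,0.040,0.021
West Sulawesi,0.206,0.151,0.081,0.139,0.102,0.055,0.110,0.081,0.043
West Sumatra,0.271,0.182,0.120,0.183,0.124,0.081,0.145,0.098,0.064
Yogyakarta,0.068,0.054,0.023,0.046,0.037,0.016,0.037,0.029,0.012
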