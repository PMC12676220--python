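province,usdot_both,usdot_male,usdot_female,oecd_both,oecd_male,oecd_female,wage_both,wage_male,wage_female
Aceh,0.352,0.293,0.110,0.239,0.199,0.075,0.189,0.157,0.059
Bali,0.179,0.121,0.079,0.121,0.082,0.053,0.096,0.065,0.042
Bangka-Belitung Islands,0.116,0.089,0.043,0.079,0.060,0.029,0.062,0.048,0.023
Banten,0.886,0.720,0.292,0.601,0.488,0.198,0.475,0.386,0.157
Bengkulu,0.127,0.101,0.044,0.086,0.068,0.030,0.068,0.054,0.024
Central Java,1.477,1.123,0.550,1.002,0.761,0.373,0.793,0.603,0.295
Central Kalimantan,0.210,0.141,0.093,0.142,0.096,0.063,0.113,0.076,0.050
Central Sulawesi,0.306,0.243,0.106,0.208,0.165,0.072,0.164,0.130,0.057
East Java,1.548,1.182,0.572,1.049,0.801,0.388,0.831,0.634,0.307
East Kalimantan,0.196,0.149,0.073,0.133,0.101,0.049,0.105,0.080,0.039
East Nusa Tenggara,0.574,0.405,0.240,0.389,0.275,0.162,0.308,0.217,0.129
Gorontalo,0.146,0.103,0.061,0.099,0.070,0.041,0.078,0.055,0.033
Indonesia,16.825,12.917,6.164,11.407,8.753,4.179,9.030,6.931,3.309
Jakarta,0.356,0.281,0.125,0.241,0.190,0.084,0.191,0.151,0.067
Jambi,0.183,0.139,0.068,0.124,0.094,0.046,0.098,0.075,0.037
Lampung,0.572,0.465,0.189,0.388,0.315,0.128,0.307,0.250,0.101
Maluku,0.209,0.145,0.090,0.142,0.098,0.061,0.112,0.078,0.048
North Kalimantan,0.067,0.053,0.024,0.046,0.036,0.016,0.036,0.028,0.013
North Maluku,0.162,0.122,0.061,0.110,0.083,0.042,0.087,0.065,0.033
North Sulawesi,0.201,0.167,0.063,0.136,0.113,0.043,0.108,0.090,0.034
North Sumatra,1.486,1.209,0.488,1.007,0.819,0.331,0.797,0.649,0.262
Papua,0.710,0.569,0.241,0.482,0.385,0.163,0.381,0.305,0.129
Riau,0.352,0.287,0.114,0.238,0.195,0.077,0.189,0.154,0.061
Riau Islands,0.122,0.113,0.029,0.083,0.076,0.020,0.065,0.061,0.016
South Kalimantan,0.324,0.245,0.122,0.220,0.166,0.083,0.174,0.132,0.066
South Sulawesi,0.608,0.475,0.216,0.412,0.322,0.147,0.326,0.255,0.116
South Sumatra,0.676,0.531,0.238,0.458,0.360,0.161,0.363,0.285,0.128
Southeast Sulawesi,0.326,0.262,0.110,0.221,0.178,0.075,0.175,0.141,0.059
West Java,2.979,2.219,1.147,2.020,1.504,0.778,1.599,1.191,0.616
West Kalimantan,0.295,0.189,0.139,0.200,0.128,0.094,0.158,0.101,0.075
West Nusa Tenggara,0.403,0.295,0.160,0.273,0.200,0.108,0.216,0.158,0.086
West Papua,0.103,0.076,0.040,0.070,0.051,0.027,0.055,0.041,0.022
West Sulawesi,0.209,0.153,0.083,0.142,0.104,0.056,0.112,0.082,0.044
West Sumatra,0.285,0.192,0.127,0.193,0.130,0.086,0.153,0.103,0.068
Yogyakarta,0.078,0.060,0.028,0.053,0.041,0.019,0.042,0.032,0.015
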