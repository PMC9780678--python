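compound_id,hERG,H-HT,Ames,ROA,Carcinogenicity,Respiratory,Non-Genotoxic_Carcinogenicity,Genotoxic_Carcinogenicity_Mutagenicity
C_0001,0.276,0.325,0.288,0.28,0.264,0.306,0.808,0.08
C_0002,0.065,0.365,0.183,0.082,0.177,0.07,0.073,0.292
C_0003,0.112,0.115,0.146,0.109,0.209,0.146,0.123,0.065
C_0004,0.189,0.329,0.382,0.21,0.299,0.334,0.342,0.245
C_0005,0.253,0.217,0.254,0.052,0.37,0.131,0.307,0.287
C_0006,0.369,0.113,0.279,0.18,0.291,0.309,0.124,0.114
C_0007,0.358,0.175,0.37,0.249,0.063,0.054,0.076,0.181
C_0008,0.388,0.253,0.249,0.293,0.095,0.16,0.061,0.235
C_0009,0.351,0.069,0.081,0.082,0.159,0.089,0.238,0.102
C_0010,0.366,0.095,0.17,0.332,0.337,0.361,0.219,0.241
C_0011,0.28,0.323,0.288,0.305,0.348,0.326,0.368,0.335
C_0012,0.339,0.06,0.252,0.262,0.356,0.162,0.132,0.361
C_0013,0.288,0.356,0.242,0.151,0.235,0.234,0.165,0.105
C_0014,0.265,0.076,0.323,0.243,0.303,0.108,0.323,0.055
C_0015,0.306,0.28,0.164,0.056,0.3,0.359,0.359,0.147
C_0016,0.312,0.212,0.279,0.371,0.378,0.325,0.199,0.372
C_0017,0.051,0.246,0.301,0.23,0.074,0.148,0.096,0.105
C_0018,0.066,0.334,0.319,0.322,0.078,0.342,0.088,0.894
C_0019,0.095,0.058,0.374,0.085,0.139,0.054,0.069,0.305
C_0020,0.3,0.347,0.396,0.183,0.083,0.307,0.347,0.197
C_0021,0.171,0.182,0.155,0.263,0.062,0.099,0.058,0.27
C_0022,0.382,0.359,0.222,0.216,0.375,0.192,0.137,0.338
C_0023,0.179,0.223,0.377,0.356,0.344,0.313,0.127,0.286
C_0024,0.311,0.121,0.104,0.224,0.932,0.179,0.14,0.323
C_0025,0.068,0.172,0.146,0.373,0.395,0.056,0.232,0.142
C_0026,0.169,0.11,0.222,0.146,0.263,0.163,0.174,0.157
C_0027,0.372,0.234,0.184,0.348,0.079,0.151,0.105,0.125
C_0028,0.07,0.224,0.214,0.301,0.295,0.239,0.271,0.212
C_0029,0.381,0.127,0.062,0.263,0.134,0.397,0.198,0.195
C_0030,0.066,0.114,0.37,0.294,0.198,0.21,0.075,0.211
C_0031,0.205,0.143,0.195,0.203,0.155,0.129,0.342,0.392
C_0032,0.239,0.077,0.22,0.111,0.346,0.393,0.332,0.247
C_0033,0.911,0.294,0.102,0.34,0.112,0.263,0.244,0.15
C_0034,0.307,0.095,0.207,0.338,0.202,0.382,0.215,0.21
C_0035,0.276,0.248,0.336,0.066,0.254,0.327,0.393,0.089
C_0036,0.372,0.111,0.054,0.624,0.167,0.394,0.197,0.118
C_0037,0.284,0.108,0.229,0.264,0.284,0.182,0.18,0.199
C_0038,0.065,0.366,0.369,0.229,0.126,0.296,0.179,0.083
C_0039,0.197,0.177,0.243,0.29,0.164,0.31,0.307,0.261
C_0040,0.34,0.184,0.099,0.36,0.271,0.134,0.15,0.087
C_0041,0.15,0.328,0.292,0.17,0.138,0.331,0.092,0.302
C_0042,0.144,0.277,0.135,0.186,0.32,0.072,0.312,0.14
C_0043,0.279,0.068,0.314,0.08,0.091,0.202,0.133,0.256
C_0044,0.094,0.378,0.235,0.218,0.268,0.112,0.331,0.255
C_0045,0.21,0.142,0.128,0.267,0.291,0.182,0.192,0.087
C_0046,0.139,0.164,0.132,0.237,0.103,0.3,0.149,0.14
C_0047,0.092,0.334,0.108,0.051,0.37,0.294,0.225,0.239
C_0048,0.221,0.237,0.205,0.31,0.295,0.167,0.215,0.383
C_0049,0.176,0.168,0.315,0.369,0.389,0.113,0.312,0.246
C_0050,0.126,0.121,0.197,0.127,0.226,0.288,0.217,0.068
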