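compound_id,mw,n_ha,n_hd,n_rot,n_ring,f_char,logp
C_0002,320.71,2,0,10,3,-1,1.73
C_0003,633.44,12,0,16,4,-1,3.28
C_0004,306.61,2,3,11,3,0,0.26
C_0005,480.64,19,6,0,1,3,3.45
C_0006,503.23,16,4,4,3,-2,1.49
C_0007,353.77,5,7,20,2,1,-0.9
C_0008,868.0,8,0,18,2,0,1.26
C_0009,852.35,5,2,14,1,-1,2.36
C_0010,502.62,1,9,5,5,1,0.96
C_0011,785.29,4,2,12,4,-1,2.4
C_0012,880.37,8,0,12,2,-1,2.64
C_0013,346.96,11,5,9,1,1,5.83
C_0014,45.3,6,8,0,5,0,1.31
C_0015,198.44,6,7,22,3,1,6.85
C_0016,41.49,12,3,8,4,0,3.93
C_0017,801.81,7,6,17,3,1,3.11
C_0018,351.96,10,1,3,2,1,-2.53
C_0019,874.81,9,6,12,2,0,4.11
C_0020,790.56,12,2,12,1,1,4.36
C_0021,328.6,11,6,2,0,1,3.27
C_0022,859.72,7,0,14,4,0,4.42
C_0023,75.69,11,11,2,2,3,3.3
C_0024,320.42,4,4,4,2,1,4.26
C_0025,489.99,2,3,11,1,1,3.57
C_0026,181.74,8,12,5,3,1,1.31
C_0027,251.52,2,2,4,1,1,2.71
C_0028,222.41,4,4,7,0,0,3.47
C_0029,256.49,3,2,8,3,2,3.32
C_0030,752.01,8,5,19,1,-1,4.47
C_0031,338.77,8,7,4,1,-1,2.17
C_0032,166.28,3,6,21,0,1,1.76
C_0033,450.27,5,4,7,0,1,1.1
C_0034,862.3,6,2,17,2,1,2.88
C_0035,646.79,7,0,5,1,0,4.72
C_0036,556.02,10,1,1,1,-1,3.13
C_0037,39.64,5,7,8,4,2,4.39
C_0038,250.32,19,2,0,1,-1,4.73
C_0039,42.41,1,6,0,3,2,2.42
C_0040,208.82,6,5,2,5,-1,-1.61
C_0041,737.53,1,6,15,1,1,4.6
C_0042,253.86,20,4,7,1,0,-2.14
C_0043,895.33,1,0,17,3,-1,3.06
C_0044,659.06,1,2,13,5,1,1.16
C_0045,39.32,10,3,10,0,-1,3.41
C_0046,398.76,13,2,0,2,3,2.38
C_0047,778.28,12,1,10,0,1,0.78
C_0048,883.97,7,1,5,5,-1,4.1
C_0049,785.11,19,5,10,2,0,4.54
C_0050,653.54,7,7,22,5,-1,4.75
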