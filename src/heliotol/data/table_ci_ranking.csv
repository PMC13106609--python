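code,name,ci,rank
V1,Qingyongjiu 471,0.666,9
V2,Qingyongjiu 465,0.668,6
V3,Qingyongjiu 458,0.600,22
V4,Qingyongjiu 488,0.255,44
V5,Qingyongjiu 085,0.550,29
V6,Qingyongjiu 084,0.205,46
V7,Zhangyan 1,0.524,31
V8,Xizangbailang,0.698,2
V9,Qingyongjiu 045,0.315,40
V10,Qingyongjiu 051,0.265,43
V11,Qingyongjiu 080,0.404,37
V12,Qingyongjiu 083,0.661,10
V13,Qingyongjiu 257,0.585,25
V14,Qingyongjiu 326,0.637,13
V15,Qingyongjiu 476,0.687,3
V16,Qingyongjiu 475,0.598,23
V17,Qingyongjiu 477,0.403,38
V18,Qingyongjiu 478,0.806,1
V19,Qingyongjiu 226,0.193,47
V20,Qingyongjiu 178,0.275,42
V21,Qingyongjiu 073,0.577,26
V22,Qingyongjiu 066,0.422,36
V23,Qingyongjiu 037,0.426,35
V24,Qingyongjiu 029,0.590,24
V25,Qingyongjiu 023,0.605,20
V26,Qingyongjiu 027,0.683,4
V27,Qingyongjiu 062,0.601,21
V28,Qingyongjiu 064,0.571,28
V29,Qingyongjiu 097,0.470,33
V30,Qingyongjiu 160,0.538,30
V31,Qingyongjiu 479,0.190,48
V32,Qingyongjiu 480,0.683,5
V33,Qingyongjiu 486,0.667,7
V34,Qingyongjiu 482,0.277,41
V35,Qingyongjiu 092,0.615,18
V36,Qingyongjiu 090,0.369,39
V37,Qingyongjiu 061,0.636,14
V38,Qingyongjiu 060,0.625,16
V39,Qingyan 5,0.231,45
V40,Menggu Oat,0.619,17
V41,Bayan 5,0.611,19
V42,Gaohan 7,0.439,34
V43,Qingyongjiu 052,0.632,15
V44,Qingyongjiu 055,0.638,12
V45,Qingyongjiu 057,0.497,32
V46,Qingyongjiu 059,0.656,11
V47,Qingyongjiu 489,0.572,27
V48,Qingyongjiu 089,0.663,9
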