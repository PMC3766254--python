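source_id,source_name,target_id,target_name,sign,level1,level2,level3,refs
2,Criminal Justice System Involvement,1,Homelessness,+,H,M,H,B11;B12;B13
2,Criminal Justice System Involvement,3,Poverty,+,VH,H,VH,B14;B15;B16
2,Criminal Justice System Involvement,4,Unemployment,+,VH,L,M,B17;B18;B19
2,Criminal Justice System Involvement,9,Family Breakdown,+,H,VH,H,B18;B20;B21
3,Poverty,1,Homelessness,+,H,H,L,B5;B22;B23
3,Poverty,7,Addiction,+,L,L,L,B24;B25;B26
4,Unemployment,1,Homelessness,+,M,L,VL,B11;B27;B28
4,Unemployment,13,Government Assistance,+,H,H,H,B29;B30;B31
5,Education,1,Homelessness,-,M,L,H,B5;B32;B22
5,Education,3,Poverty,-,H,VH,H,B33;B34;B35
5,Education,4,Unemployment,-,VH,H,H,B36;B37;B38
5,Education,6,Income,+,H,H,H,B39;B40;B41
6,Income,1,Homelessness,-,VH,H,M,B13;B42;B41
7,Addiction,1,Homelessness,+,M,H,VH,B5;B43;B44
7,Addiction,2,Criminal Justice System Involvement,+,H,M,VH,B11;B45;B46
7,Addiction,10,Mental Illness,+,M,H,M,B47;B48;B49
7,Addiction,9,Family Breakdown,+,VH,H,H,B50;B51;B51
8,Social Support Network,7,Addiction,-,M,M,M,B52;B53;B54
8,Social Support Network,9,Family Breakdown,-,VL,M,M,B55;B56;B57
9,Family Breakdown,1,Homelessness,+,VH,H,M,B58;B59;B60
9,Family Breakdown,7,Addiction,+,VH,M,H,B50;B50;B51
9,Family Breakdown,12,Childhood Homelessness,+,H,H,M,B61;B62;B63
10,Mental Illness,1,Homelessness,+,H,L,L,B5;B44;B45
10,Mental Illness,2,Criminal Justice System Involvement,+,VH,L,M,B64;B65;B45
10,Mental Illness,7,Addiction,+,VH,M,M,B66;B67;B49
10,Mental Illness,9,Family Breakdown,+,H,M,H,B68;B69;B70
11,Non-Government Assistance,1,Homelessness,-,H,L,M,B71;B72;B73
12,Childhood Homelessness,5,Education,-,M,M,H,B74;B75;B76
13,Government Assistance,1,Homelessness,-,M,M,VH,B77;B78;B79
14,Cost of Housing,1,Homelessness,+,H,VL,M,B80;B44;B81
3,Poverty,9,Family Breakdown,+,M,M,H,B82;B83;B84
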