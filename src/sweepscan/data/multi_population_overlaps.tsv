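chrom	sweep_start	sweep_end	overlap_start	overlap_end	populations
1	179100000	181800000	180000000	181800000	Nset,RP
2	48600000	51300000	49500000	51300000	L5,L6
2	58200000	60300000	59700000	60300000	BvSW,L3
2	83700000	85200000	83700000	85200000	L1,L7
3	27600000	34200000	28800000	30300000	L1,L5
3	35100000	37200000	35700000	37200000	L1,L2,L4
3	96000000	97800000	96900000	97800000	L1,L2,L5
3	96900000	99900000	98400000	99600000	L2,L5,Nset
4	48600000	51000000	49200000	51000000	L2,L6
5	6900000	9000000	7800000	8400000	L1,L4,L6,RP,BvSW
5	41100000	42900000	41100000	42000000	L1,L3,L5,L6,L7
6	7800000	9900000	7800000	9600000	L1,L7
6	25200000	27900000	26700000	27900000	L2,L3
7	9900000	12600000	9900000	11700000	L1,L4,RP,BvSW
8	300000	3300000	1200000	3000000	L3,L5
9	12600000	14400000	13800000	14400000	L4,L6
9	15900000	19500000	15600000	16200000	L3,L5,L6
9	15900000	19500000	17400000	18600000	L3,L5,L6,Nset,BvSW
10	16800000	20100000	17400000	19200000	L2,L5,RP
11	1200000	8400000	4200000	7500000	L2,L4,L7,RP
11	7800000	12000000	9900000	12000000	L3,L4
14	3000000	4500000	3300000	4500000	L1,L3,L6,BvSW
22	300000	2100000	600000	2100000	L1,L3,L6
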