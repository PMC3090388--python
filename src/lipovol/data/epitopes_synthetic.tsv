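antibody	residue_range	latitude_deg	longitude_deg	is_anchor
MB19	71	62.0	-15.0	True
MB24	405-539	35.0	40.0	True
MB11	995-1082	10.0	85.0	True
2D8	1438-1480	-12.0	120.0	False
B4	1854-1878	-35.0	150.0	False
B3	2239-2331	-48.0	-160.0	False
4G3	2980-3084	-30.0	-110.0	False
MB47	3429-3453,3507-3523	-8.0	-75.0	False
MB43	4027-4081	15.0	-50.0	False
Bsol16	4154-4189	33.0	-30.0	False
Bsol7	4517-4536	50.0	-5.0	False
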