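# 15-beam edge sweep for an Elekta 80-leaf MLC computed by a commercial TPS
# (Pinnacle 9.2) with the vendor default RLO table in force.  Columns 2-3 are
# the TPS's 50%-intensity field edges; columns 5-7 are the update-rule output
# as printed (the averages were formed from the TPS's unrounded values).
Displayed Leaf Position (cm)	Y2 Leaf Edge (cm)	Y1 Leaf Edge (cm)	RLO Values (cm)	Y2 Modified RLO (cm)	Y1 Modified RLO (cm)	Av. of Y1 and Y2 Modified RLO (cm)
-10.0	-9.9302	-9.9065	-0.2234	-0.1536	-0.1299	-0.1418
-8.0	-7.9388	-7.9064	-0.1431	-0.0819	-0.0495	-0.0657
-6.0	-5.9343	-5.9059	-0.0805	-0.0148	0.0136	-0.0006
-4.0	-3.9435	-3.9166	-0.0358	0.0207	0.0476	0.0342
-2.0	-1.9355	-1.9134	-0.0090	0.0555	0.0776	0.0665
0.0	0.0726	0.1006	0.0000	0.0726	0.1006	0.0866
2.0	2.0745	2.1085	-0.0090	0.0655	0.0995	0.0825
4.0	4.0879	4.1325	-0.0358	0.0521	0.0967	0.0744
6.0	6.0881	6.1366	-0.0805	0.0076	0.0561	0.0318
8.0	8.0961	8.1309	-0.1431	-0.0470	-0.0122	-0.0296
10.0	10.0939	10.1371	-0.2234	-0.1295	-0.0863	-0.1079
12.0	12.0988	12.1284	-0.3213	-0.2225	-0.1929	-0.2077
14.0	14.1932	14.2168	-0.4368	-0.2436	-0.2200	-0.2318
16.0	16.3061	16.3289	-0.5697	-0.2636	-0.2408	-0.2522
18.0	18.4682	18.4936	-0.7198	-0.2516	-0.2262	-0.2389
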