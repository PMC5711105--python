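# 15-beam edge sweep for an Elekta 80-leaf MLC computed by a commercial TPS
# (Pinnacle 9.2) with an all-zero RLO table in force.  Columns 2-3 are the
# TPS's 50%-intensity field edges; columns 5-7 are the update-rule output as
# printed (the averages were formed from the TPS's unrounded values).
Displayed Leaf Position (cm)	Y2 Leaf Edge (cm)	Y1 Leaf Edge (cm)	RLO Values (cm)	Y2 Modified RLO (cm)	Y1 Modified RLO (cm)	Av. of Y1 and Y2 Modified RLO (cm)
-10.0	-10.1397	-10.1124	0.0	-0.1397	-0.1124	-0.1260
-8.0	-8.0487	-8.0291	0.0	-0.0487	-0.0291	-0.0389
-6.0	-6.0261	-5.9951	0.0	-0.0261	0.0049	-0.0106
-4.0	-3.9558	-3.9368	0.0	0.0442	0.0632	0.0537
-2.0	-1.9476	-1.9164	0.0	0.0524	0.0836	0.0680
0.0	0.0739	0.1028	0.0	0.0739	0.1028	0.0884
2.0	2.0619	2.1036	0.0	0.0619	0.1036	0.0828
4.0	4.0704	4.1149	0.0	0.0704	0.1149	0.0926
6.0	6.0046	6.0446	0.0	0.0046	0.0446	0.0246
8.0	7.9748	8.0077	0.0	-0.0252	0.0077	-0.0087
10.0	9.8820	9.9144	0.0	-0.1180	-0.0856	-0.1018
12.0	11.7838	11.8183	0.0	-0.2162	-0.1817	-0.1989
14.0	13.7693	13.7939	0.0	-0.2307	-0.2061	-0.2184
16.0	15.7670	15.7940	0.0	-0.2330	-0.2060	-0.2195
18.0	17.7646	17.7863	0.0	-0.2354	-0.2137	-0.2246
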