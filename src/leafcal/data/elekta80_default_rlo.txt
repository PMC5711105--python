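# Vendor default RLO table for an Elekta 80-leaf MLC as shipped with a
# commercial TPS (Pinnacle 9.2): position_cm offset_cm.  All offsets <= 0,
# i.e. leaves are always retracted before the dose is calculated.
-10.0000 -0.2234
-8.0000 -0.1431
-6.0000 -0.0805
-4.0000 -0.0358
-2.0000 -0.0090
0.0000 0.0000
2.0000 -0.0090
4.0000 -0.0358
6.0000 -0.0805
8.0000 -0.1431
10.0000 -0.2234
12.0000 -0.3213
14.0000 -0.4368
16.0000 -0.5697
18.0000 -0.7198
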