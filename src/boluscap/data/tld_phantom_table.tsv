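location	abs_percent_diff
1	3.4
2	2.1
3	2.0
4	3.1
5	1.5
6	1.7
7	2.4
8	1.7
9	1.9
10	4.6
11	3.6
12	1.1
13	6.3
14	2.0
15	3.7
16	1.0
17	0.1
18	1.8
19	0.5
20	4.1
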