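1	274330532	0	60	61
2	151935994	0	60	61
3	132848913	0	60	61
4	130910915	0	60	61
5	104526007	0	60	61
6	170843587	0	60	61
7	121844099	0	60	61
8	138966237	0	60	61
9	139512083	0	60	61
10	69359453	0	60	61
11	79169978	0	60	61
12	61602749	0	60	61
13	208334590	0	60	61
14	141755446	0	60	61
15	140412725	0	60	61
16	79944280	0	60	61
17	63494081	0	60	61
18	55982971	0	60	61
X	125939595	0	60	61
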