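# Post-split faction membership: Instructor (Mr. Hi, node 1) vs President (Officer, node 34).
1	Instructor
2	Instructor
3	Instructor
4	Instructor
5	Instructor
6	Instructor
7	Instructor
8	Instructor
9	Instructor
10	President
11	Instructor
12	Instructor
13	Instructor
14	Instructor
15	President
16	President
17	Instructor
18	Instructor
19	President
20	Instructor
21	President
22	Instructor
23	President
24	President
25	President
26	President
27	President
28	President
29	President
30	President
31	President
32	President
33	President
34	President
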