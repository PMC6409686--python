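1	TYPE2
2	TYPE3
3	TYPE1
4	TYPE1
5	TYPE1
6	TYPE1
7	TYPE1
8	TYPE1
9	TYPE3
10	TYPE2
11	TYPE2
12	TYPE3
13	TYPE3
14	TYPE2
15	TYPE2
16	TYPE2
17	TYPE3
18	TYPE2
19	TYPE3
20	TYPE3
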