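age_band,label,persons
0,0-4,1282357
1,5-9,1351664
2,10-14,1353177
3,15-19,1352745
4,20-24,1302412
5,25-29,1407081
6,30-34,1466615
7,35-39,1492204
8,40-44,1479257
9,45-49,1358594
10,50-54,1300777
11,55-59,1008799
12,60-64,822024
13,65-69,682513
14,70-74,638380
15,75-79,519356
16,80-84,330050
17,85+,265235
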