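item_id,condition,target_strength,distractor_strength,uv_target_strength,uv_distractor_strength
1,CV,80,0,0,0
2,CV,56.66,0,0,0
3,CV,70,0,0,6.66
4,CV,73.33,0,0,6.66
5,CV,60,0,0,0
6,CV,66.66,0,0,3.33
7,CV,66.66,0,0,0
8,CV,46.66,0,0,0
9,CV,63.33,0,0,0
10,CV,53.33,0,0,0
11,CV,53.33,0,0,0
12,CV,46.66,0,0,0
13,CV,73.33,0,0,0
14,CV,56.66,0,0,0
15,MV,23.33,0,0,0
16,MV,16.66,0,0,0
17,MV,20,0,0,0
18,MV,6.66,0,0,0
19,MV,13.33,0,0,13.33
20,MV,23.33,0,0,6.66
21,MV,16.66,0,0,0
22,MV,10,0,16.66,0
23,MV,20,6.66,0,6.66
24,MV,20,0,0,0
25,MV,6.66,0,0,0
26,MV,13.33,3.33,0,0
27,MV,20,0,0,0
28,MV,3.33,0,0,0
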