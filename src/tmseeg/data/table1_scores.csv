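subject_id,age,psqi_before,isi_before,psqi_after,isi_after
1,56,14,15,10,11
2,39,16,28,12,18
3,18,12,20,10,15
4,47,14,12,8,10
5,38,17,20,15,16
6,53,18,23,16,15
7,33,15,26,10,16
8,44,18,18,10,13
9,38,11,8,9,7
10,56,9,9,15,15
11,42,18,27,14,16
12,47,17,17,11,8
13,37,14,13,12,11
14,32,18,21,16,17
15,50,19,28,13,14
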