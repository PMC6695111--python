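year,cumulative_survival
1,0.995838
2,0.992927
3,0.990016
4,0.987105
5,0.984194
6,0.981283
7,0.978372
8,0.975461
9,0.97255
10,0.969639
11,0.966728
12,0.963817
13,0.960906
14,0.957995
15,0.955084
16,0.952173
17,0.949262
18,0.9463509999999999
19,0.9434400000000001
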