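age,qx
0,0.0002188987634916817
1,0.00022079062001789662
2,0.00022287165806189613
3,0.00022516079490730867
4,0.00022767883938346056
5,0.00023044868098220928
6,0.00023349549787776702
7,0.00023684698573833707
8,0.00024053360940845536
9,0.00024458887974410093
10,0.000249049658114453
11,0.000253956491333418
12,0.0002593539800583855
13,0.0002652911839988725
14,0.00027182206760856253
15,0.0002790059903026165
16,0.00028690824564181483
17,0.00029560065437017613
18,0.0003051622166768686
19,0.0003156798295889107
20,0.00032724907598680186
21,0.0003399750923820388
22,0.00035397352330157617
23,0.00036937157090699557
24,0.00038630914932569205
25,0.0004049401541159625
26,0.0004254338583133954
27,0.00044797644764371647
28,0.00047277270872336796
29,0.0005000478854362278
30,0.0005300497201694565
31,0.0005630506982298167
32,0.0005993505155609258
33,0.000639278791852993
34,0.0006831980532938653
35,0.0007315070115755384
36,0.0007846441683593275
37,0.0008430917772311863
38,0.0009073801982776297
39,0.0009780926837945625
40,0.0010558706373364757
41,0.0011414193923414695
42,0.0012355145609656004
43,0.0013390090085431128
44,0.001452840514296061
45,0.0015780401845731928
46,0.0017157416910366097
47,0.0018671914128630673
48,0.002033759569218474
49,0.0022169524360230453
50,0.0024184257493851113
51,0.002639999407053284
52,0.0028836735888475573
53,0.003151646427291155
54,0.0034463333705552213
55,0.0037703883913698943
56,0.004126727207676151
57,0.004518552693473121
58,0.004949382671456504
59,0.005423080292526805
60,0.00594388722092809
61,0.006516459857416335
62,0.007145908846195592
63,0.007837842124009065
64,0.008598411781281512
65,0.009434365014972523
66,0.01035309946008367
67,0.01136272319064413
68,0.01247211968032591
69,0.013691018006233291
70,0.015030068565138666
71,0.016500924547437013
72,0.018116329377852902
73,0.019890210280431586
74,0.021837778054989432
75,0.02397563305868111
76,0.026321877264609106
77,0.0288962321134697
78,0.03172016167716463
79,0.03481700040701685
80,0.03821208443446422
81,0.041932885018308275
82,0.046009142277926185
83,0.05047299680314887
84,0.05535911607447919
85,0.060704811846713835
86,0.06655014372912549
87,0.07293800312062848
88,0.07991417041446447
89,0.08752733696230153
90,0.09582908167532034
91,0.1048737903404865
92,0.11471850375554093
93,0.1254226786639583
94,0.13704784325087316
95,0.149657126721782
96,0.16331464034517207
97,0.17808468546456668
98,0.1940307626021398
99,0.211214355185955
100,1.0
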