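age,sex,qx
50,F,0.0014268672805340943
51,F,0.0015449940632912273
52,F,0.0016781648791320825
53,F,0.0018282932516824335
54,F,0.001997535441696008
55,F,0.002188321061871723
56,F,0.002403387504761323
57,F,0.0026458186455562416
58,F,0.002919088333853681
59,F,0.003227109245721005
60,F,0.003574287729656067
61,F,0.003965585347436296
62,F,0.004406587883262758
63,F,0.004903582671722417
64,F,0.005463645176334686
65,F,0.006094735834822229
66,F,0.006805808273282032
67,F,0.0076069300769492365
68,F,0.0085094173872311
69,F,0.009525984668945164
70,F,0.010670911052624299
71,F,0.0119602246968592
72,F,0.013411906625112824
73,F,0.01504611545749801
74,F,0.01688543436417822
75,F,0.0189551413923299
76,F,0.021283504036329615
77,F,0.023902098497547652
78,F,0.02684615347411623
79,F,0.030154917480802235
80,F,0.03387204756166551
81,F,0.038046015747384754
82,F,0.04273052763408369
83,F,0.0479849449143831
84,F,0.05387470045112164
85,F,0.06047169041129774
86,F,0.06785462292181699
87,F,0.07610929651377585
88,F,0.08532877413907469
89,F,0.09561340964877096
90,F,0.10707067324894293
91,F,0.11981471062810911
92,F,0.13396555737232807
93,F,0.1496479163871295
94,F,0.16698939212323194
95,F,0.1861180627479564
96,F,0.20715926197792034
97,F,0.2302314389146347
98,F,0.25544097078314587
99,F,0.28287582505983333
100,F,0.3125980104534486
101,F,0.344634828054752
102,F,0.3789690427797464
103,F,0.4155282486135031
104,F,0.45417390438292704
105,F,0.4946907698540536
106,F,0.536777765517428
107,F,0.5800415896392914
108,F,0.6239947090433284
109,F,0.6680595269215065
110,F,1.0
50,M,0.003430309503633877
51,M,0.0036127764746060054
52,M,0.003818467340595766
53,M,0.004050332216902097
54,M,0.00431169440853485
55,M,0.004606297195045461
56,M,0.004938356365305596
57,M,0.0053126191773923415
58,M,0.005734430489266806
59,M,0.006209806881293467
60,M,0.006745519671382261
61,M,0.0073491878067949434
62,M,0.008029381702180372
63,M,0.008795739179276119
64,M,0.00965909474725657
65,M,0.010631623540193202
66,M,0.011727001294466022
67,M,0.012960581797486825
68,M,0.01434959326084484
69,M,0.01591335505436209
70,M,0.017673516167516112
71,M,0.019654316622014334
72,M,0.02188287281953427
73,M,0.024389487440953372
74,M,0.02720798397927482
75,M,0.03037606524017067
76,M,0.03393569412306641
77,M,0.0379334936308493
78,M,0.04242116126230622
79,M,0.04745589061744604
80,M,0.05310079007482382
81,M,0.059425284648908394
82,M,0.06650548245792831
83,M,0.07442448147378433
84,M,0.083272585232403
85,M,0.09314738782006748
86,M,0.10415367862697256
87,M,0.11640310606300042
88,M,0.13001352678805222
89,M,0.14510795335720283
90,M,0.16181299916945913
91,M,0.18025670633117075
92,M,0.20056563119827953
93,M,0.222861056432633
94,M,0.24725420087031058
95,M,0.27384031399202635
96,M,0.3026915762103165
97,M,0.33384878665102236
98,M,0.36731191455303924
99,M,0.40302972678083937
100,M,0.44088888861692266
101,M,0.4807031702793013
102,M,0.5222036720629439
103,M,0.5650312886664779
104,M,0.6087329320780148
105,M,0.6527632630000155
106,M,0.6964937577989674
107,M,0.7392307530437112
108,M,0.7802435450139869
109,M,0.8188025781763768
110,M,1.0
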