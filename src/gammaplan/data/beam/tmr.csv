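depth_mm,tmr
0.0,1.0
1.0,0.9960079893439915
2.0,0.9920319148370607
3.0,0.9880717128619305
4.0,0.9841273200552851
5.0,0.9801986733067553
6.0,0.9762857097579093
7.0,0.9723883668012469
8.0,0.9685065820791976
9.0,0.9646402934831231
10.0,0.9607894391523232
11.0,0.9569539574730467
12.0,0.9531337870775047
13.0,0.9493288668428895
14.0,0.9455391358903963
15.0,0.9417645335842487
16.0,0.9380049995307295
17.0,0.9342604735772135
18.0,0.9305308958112057
19.0,0.9268162065593822
20.0,0.9231163463866358
21.0,0.9194312560951247
22.0,0.9157608767233256
23.0,0.9121051495450904
24.0,0.9084640160687061
25.0,0.9048374180359595
26.0,0.9012252974212047
27.0,0.8976275964304349
28.0,0.8940442575003572
29.0,0.8904752232974726
30.0,0.8869204367171575
31.0,0.8833798408827509
32.0,0.8798533791446438
33.0,0.8763409950793734
34.0,0.8728426324887193
35.0,0.8693582353988059
36.0,0.865887748059205
37.0,0.8624311149420455
38.0,0.8589882807411234
39.0,0.8555591903710185
40.0,0.8521437889662113
41.0,0.8487420218802068
42.0,0.8453538346846587
43.0,0.8419791731684999
44.0,0.838617983337074
45.0,0.835270211411272
46.0,0.8319358038266718
47.0,0.8286147072326806
48.0,0.8253068684916823
49.0,0.8220122346781865
50.0,0.8187307530779818
51.0,0.8154623711872927
52.0,0.812207036711939
53.0,0.8089646975664998
54.0,0.8057353018734796
55.0,0.8025187979624785
56.0,0.7993151343693651
57.0,0.7961242598354537
58.0,0.7929461233066837
59.0,0.7897806739328027
60.0,0.7866278610665534
61.0,0.7834876342628625
62.0,0.7803599432780343
63.0,0.7772447380689461
64.0,0.7741419687922484
65.0,0.7710515858035663
66.0,0.7679735396567061
67.0,0.764907781102864
68.0,0.7618542610898376
69.0,0.7588129307612413
70.0,0.7557837414557255
71.0,0.7527666447061961
72.0,0.7497615922390413
73.0,0.7467685359733571
74.0,0.7437874280201796
75.0,0.7408182206817179
76.0,0.7378608664505911
77.0,0.7349153180090687
78.0,0.7319815282283126
79.0,0.7290594501676237
80.0,0.7261490370736909
81.0,0.7232502423798424
82.0,0.7203630197053014
83.0,0.7174873228544433
84.0,0.7146231058160573
85.0,0.7117703227626097
86.0,0.7089289280495107
87.0,0.7060988762143844
88.0,0.7032801219763409
89.0,0.7004726202352524
90.0,0.697676326071031
91.0,0.6948911947429106
92.0,0.6921171816887304
93.0,0.6893542425242224
94.0,0.686602333042301
95.0,0.6838614092123558
96.0,0.6811314271795471
97.0,0.678412343264104
98.0,0.675704113960626
99.0,0.6730066959373864
100.0,0.6703200460356393
101.0,0.6676441212689289
102.0,0.6649788788224019
103.0,0.6623242760521222
104.0,0.659680270484389
105.0,0.6570468198150567
106.0,0.6544238819088586
107.0,0.651811414798732
108.0,0.6492093766851474
109.0,0.6466177259354396
110.0,0.6440364210831413
111.0,0.6414654208273198
112.0,0.6389046840319162
113.0,0.6363541697250871
114.0,0.633813837098549
115.0,0.631283645506926
116.0,0.6287635544670984
117.0,0.6262535236575559
118.0,0.623753512917752
119.0,0.6212634822474616
120.0,0.6187833918061408
121.0,0.6163132019122897
122.0,0.613852873042817
123.0,0.6114023658324087
124.0,0.6089616410728969
125.0,0.6065306597126334
126.0,0.6041093828558647
127.0,0.6016977717621094
128.0,0.5992957878455384
129.0,0.596903392674358
130.0,0.5945205479701943
131.0,0.5921472156074813
132.0,0.5897833576128504
133.0,0.5874289361645234
134.0,0.5850839135917069
135.0,0.5827482523739896
136.0,0.5804219151407424
137.0,0.5781048646705196
138.0,0.5757970638904645
139.0,0.5734984758757153
140.0,0.5712090638488149
141.0,0.5689287911791218
142.0,0.5666576213822246
143.0,0.5643955181193583
144.0,0.5621424451968224
145.0,0.559898366565402
146.0,0.5576632463197913
147.0,0.5554370486980182
148.0,0.5532197380808739
149.0,0.5510112789913407
150.0,0.5488116360940264
151.0,0.5466207741945976
152.0,0.5444386582392171
153.0,0.5422652533139832
154.0,0.5401005246443706
155.0,0.5379444375946745
156.0,0.535796957667456
157.0,0.5336580505029906
158.0,0.5315276818787179
159.0,0.5294058177086945
160.0,0.5272924240430485
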