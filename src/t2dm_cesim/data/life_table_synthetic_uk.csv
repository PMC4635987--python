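age_lo,age_hi,sex,q_annual
18,19,male,0.00021676225481659372
19,20,male,0.00023717326395522598
20,21,male,0.0002595059878484074
21,22,male,0.00028394130846587373
22,23,male,0.00031067712364485356
23,24,male,0.0003399299458879401
24,25,male,0.00037193665100487827
25,26,male,0.00040695639056764765
26,27,male,0.0004452726834373033
27,28,male,0.00048719570301936077
28,29,male,0.0005330647784413944
29,30,male,0.0005832511295018605
30,31,male,0.000638160857061254
31,32,male,0.0006982382125095832
32,33,male,0.0007639691720944253
33,34,male,0.0008358853442205216
34,35,male,0.0009145682403611799
35,36,male,0.0010006539429686656
36,37,male,0.0010948382067440532
37,38,male,0.0011978820328509832
38,39,male,0.001310617759145094
39,40,male,0.0014339557132569958
40,41,male,0.0015688914794341757
41,42,male,0.0017165138344288344
42,43,male,0.0018780134124318781
43,44,male,0.0020546921641140248
44,45,male,0.0022479736802584194
45,46,male,0.0024594144562650744
46,47,male,0.002690716179982733
47,48,male,0.0029437391318916095
48,49,male,0.003220516793601247
49,50,male,0.0035232717679591907
50,51,male,0.0038544331217370553
51,52,male,0.004216655269874248
52,53,male,0.0046128385285451046
53,54,male,0.0050461514728198376
54,55,male,0.005520055243330546
55,56,male,0.006038329955003197
56,57,male,0.006605103369441978
57,58,male,0.007224882000745225
58,59,male,0.007902584832170101
59,60,male,0.008643579827825043
60,61,male,0.009453723429094563
61,62,male,0.010339403229317368
62,63,male,0.011307584021787997
63,64,male,0.012365857414725512
64,65,male,0.013522495201643392
65,66,male,0.014786506665515953
66,67,male,0.01616769997908507
67,68,male,0.017676747840125406
68,69,male,0.0193252574477627
69,70,male,0.02112584488199254
70,71,male,0.0230922138909464
71,72,male,0.025239239016427217
72,73,male,0.02758305289445051
73,74,male,0.030141137450229505
74,75,male,0.032932418561805954
75,76,male,0.035977363588392985
76,77,male,0.039298080942729796
77,78,male,0.04291842062505169
78,79,male,0.046864074322510274
79,80,male,0.05116267330436175
80,81,male,0.05584388190163436
81,82,male,0.06093948384155767
82,83,male,0.06648345810290901
83,84,male,0.07251204025986047
84,85,male,0.07906376448111241
85,86,male,0.08617948044160195
86,87,male,0.09390233838230011
87,88,male,0.10227773441982324
88,89,male,0.11135320696810314
89,90,male,0.12117827380357615
90,91,male,0.13180419790917053
91,92,male,0.14328366881117982
92,93,male,0.15567038473688444
93,94,male,0.16901851965363412
94,95,male,0.18338205821633147
95,96,male,0.1988139810006756
96,97,male,0.21536528232771224
97,98,male,0.23308380373393356
98,99,male,0.25201286800595224
99,100,male,0.2721897020317853
100,101,male,0.2936436419249904
101,102,male,0.3163941214001702
102,103,male,0.34044845468619345
103,104,male,0.36579943881119814
104,105,male,0.39242281726730954
105,106,male,0.4202746681034323
106,107,male,0.4492888043901554
107,108,male,0.47937430335351927
108,109,male,0.5104133113354893
109,110,male,0.5422593034260066
18,19,female,0.0001300629917654339
19,20,female,0.00014231070925918576
20,21,female,0.00015571167489081272
21,22,female,0.0001703744610817015
22,23,female,0.00018641785829953683
23,24,female,0.00020397183601705837
24,25,female,0.00022317859390952322
25,26,female,0.00024419371173622917
26,27,female,0.00026718740713904676
27,28,female,0.0002923459114477778
28,29,female,0.00031987297451707697
29,30,female,0.00034999151064163403
30,31,female,0.0003829453987097553
31,32,female,0.00041900145096918084
32,33,female,0.00045845156610546667
33,34,female,0.0005016150837717781
34,35,female,0.0005488413592869001
35,36,female,0.000600512578922463
36,37,female,0.0006570468380702188
37,38,female,0.0007189015066001447
38,39,female,0.0007865769079268281
39,40,female,0.00086062034069323
40,41,female,0.0009416304745765158
41,42,female,0.001030262154542605
42,43,female,0.0011272316509262081
43,44,female,0.0012333223960221407
44,45,female,0.001349391251447618
45,46,female,0.001476375354399817
46,47,female,0.0016152995950984295
47,48,female,0.0017672847821912363
48,49,female,0.001933556557723537
49,50,female,0.002115455128452015
50,51,female,0.002314445885823635
51,52,female,0.002532130992859205
52,53,female,0.002770262022485648
53,54,female,0.0030307537385463323
54,55,female,0.0033156991177925033
55,56,female,0.003627385718596332
56,57,female,0.003968313509920662
57,58,female,0.004341214282179151
58,59,female,0.004749072769992035
59,60,female,0.005195149625398021
60,61,female,0.005683006388742307
61,62,female,0.006216532613089076
62,63,female,0.006799975306445494
63,64,female,0.007437970864127119
64,65,female,0.008135579670987436
65,66,female,0.008898323559635712
66,67,female,0.009732226315798398
67,68,female,0.01064385742512719
68,69,female,0.011640379256420808
69,70,female,0.012729597873681775
70,71,female,0.013920017662763295
71,72,female,0.015220899946527866
72,73,female,0.01664232574412905
73,74,female,0.01819526280372641
74,75,female,0.019891637001819507
75,76,female,0.02174440815430101
76,77,female,0.02376765022172589
77,78,female,0.0259766358112562
78,79,female,0.028387924776768436
79,80,female,0.031019456592772054
80,81,female,0.033890646022460946
81,82,female,0.037022481410218355
82,83,female,0.04043762469830536
83,84,female,0.044160511989671525
84,85,female,0.04821745314659687
85,86,female,0.05263672852019563
86,87,female,0.057448680440290056
87,88,female,0.0626857965499138
88,89,female,0.06838278143490706
89,90,female,0.0745766122681405
90,91,female,0.0813065733524827
91,92,female,0.08861426350096424
92,93,female,0.09654356913422613
93,94,female,0.10514059480626314
94,95,female,0.11445354159832488
95,96,female,0.1245325224654108
96,97,female,0.135429302210188
97,98,female,0.14719694834177244
98,99,female,0.15988937771848932
99,100,female,0.1735607826682355
100,101,female,0.18826491935226308
101,102,female,0.20405424065249622
102,103,female,0.22097885602756073
103,104,female,0.23908530185808308
104,105,female,0.2584151081014515
105,106,female,0.27900315096913875
106,107,female,0.30087578724494635
107,108,female,0.32404877423625766
108,109,female,0.3485249906607131
109,110,female,0.37429198845672795
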