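energy_MeV_per_u,stopping_keV_per_um
0.001,17.6
0.00114841162095,18.766465722
0.00131884925112,20.0136830084
0.00151458180627,21.3473228942
0.00173936334719,22.7734520778
0.00199750508096,24.2985597393
0.00229395804788,25.9295860738
0.00263440808015,27.6765912297
0.00302538485356,29.5692614094
0.00347438712366,31.6047982451
0.00399002654848,33.7667515625
0.00458219285616,36.0319946112
0.00526224352543,38.3767871571
0.00604322161685,40.8451509976
0.00694010593275,43.4337032804
0.00797009830377,46.1129251572
0.00915295351214,48.8453177467
0.0105113581793,51.5974315501
0.0120713658851,54.4628674963
0.0138628968631,57.4395909748
0.0159203118576,60.4777429428
0.0182830711463,63.5167396058
0.020996491371,66.4850793249
0.0241126146896,69.3008470023
0.0276912069209,71.9971697154
0.031800903826,74.663046748
0.0365205275104,76.9306311274
0.0419405981961,78.4410722005
0.0481650703578,79.6878228563
0.0553133265226,80.7963633804
0.0635224669718,81.6653367427
0.0729499392616,82.191039202
0.0837765579953,82.2719034725
0.0962099727647,81.934632406
0.110488650774,80.9169734389
0.126886450532,78.2928785246
0.145717874331,74.6771106121
0.167344100261,70.7208361528
0.192179909437,66.9751852788
0.22070164131,63.6118852446
0.253456329642,60.1240834035
0.291072194364,56.5742505582
0.334270690542,53.037292676
0.38388034556,49.5137565782
0.440852649894,45.995665966
0.506280306263,42.4827292636
0.581418187169,38.9009759212
0.667707402774,35.3442999161
0.766802940738,31.9757240328
0.88060540812,28.8075937313
1.01129748415,25.8823469455
1.16138578304,23.3964406118
1.33374892964,21.2084955014
1.53169277022,19.2449264102
1.75901377704,17.4502383129
2.02007186296,15.7834028814
2.31987400257,14.2422113522
2.66417026369,12.8351259888
3.059564091,11.5545287699
3.51363895713,10.3924322028
4.03510381018,9.34067987263
4.63396010734,8.39111299464
5.32169363827,7.53462007958
6.1114948173,6.75737849022
7.01851166955,6.05480647441
8.06014036305,5.42322778509
9.25635885939,4.85826729579
10.6301100818,4.35513814353
12.2077419499,3.90752573899
14.0195127207,3.50748201245
16.1001713285,3.14827957367
18.4896238529,2.82439806949
21.2336988996,2.53130126786
24.3850265719,2.26525774955
28.0040478923,2.0220903959
32.1601740331,1.80002876377
36.9331175912,1.60077399598
42.4144214395,1.42477043271
48.7092144769,1.27150087973
55.9382279524,1.13830314496
64.2401110357,1.02056706871
73.7740900443,0.916558467444
84.7230223317,0.8247721152
97.2969034074,0.743846117799
111.736894555,0.671864614951
128.319948196,0.607132293356
147.364119707,0.549816096866
169.234667582,0.499856281874
194.351058918,0.457011870457
223.195014605,0.42016837527
256.31974851,0.38732042182
294.360577867,0.35806795318
338.047108371,0.332089927204
388.21722768,0.309092390202
445.83317572,0.288808820307
512,0.271
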