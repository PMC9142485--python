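Cz	0.0000	6.3745	129.7740
CCPz	0.0000	-10.6205	129.3712
FCCz	0.0000	23.5928	126.8526
CPz	0.0000	-27.0638	125.8344
FCz	0.0000	40.0245	120.6104
CPPz	0.0000	-42.2190	119.4830
FFCz	0.0000	54.9061	111.3115
Pz	0.0000	-55.9357	110.5067
Fz	0.0000	67.6230	99.3896
PPOz	0.0000	-67.9279	99.0407
AFFz	0.0000	77.6537	85.4961
POz	0.0000	-77.8792	85.1091
AFz	0.0000	84.7701	70.2329
POOz	0.0000	-85.1172	69.2416
AFpz	0.0000	88.8628	54.2618
Oz	0.0000	-89.1282	52.4965
Fpz	0.0000	89.9735	37.8157
OIz	0.0000	-89.9043	35.8505
C1h	-17.4627	6.3107	128.0638
C2h	17.4627	6.3107	128.0638
CCP1h	-17.3604	-10.8090	127.6458
CCP2h	17.3604	-10.8090	127.6458
FCC1h	-17.2598	23.6911	125.0931
FCC2h	17.2598	23.6911	125.0931
CP1h	-16.5310	-27.0001	124.2480
CP2h	16.5310	-27.0001	124.2480
C1	-34.6500	6.0284	122.8434
C2	34.6500	6.0284	122.8434
CCP1	-34.3624	-11.0832	122.4402
CCP2	34.3624	-11.0832	122.4402
FCC1	-34.2075	23.5359	119.8493
FCC2	34.2075	23.5359	119.8493
CP1	-32.5201	-27.2459	119.3732
CP2	32.5201	-27.2459	119.3732
FC1h	-16.4484	39.8989	118.9780
FC2h	16.4484	39.8989	118.9780
CPP1h	-15.1050	-42.3239	117.9777
CPP2h	15.1050	-42.3239	117.9777
C3h	-50.7041	5.5589	114.1498
C4h	50.7041	5.5589	114.1498
CCP3h	-50.1380	-11.5268	113.8466
CCP4h	50.1380	-11.5268	113.8466
FC1	-32.3684	39.9172	113.8844
FC2	32.3684	39.9172	113.8844
CPP1	-29.6763	-42.3844	113.6402
CPP2	29.6763	-42.3844	113.6402
CP3h	-47.3085	-27.7480	111.3579
CP4h	47.3085	-27.7480	111.3579
FCC3h	-50.0729	23.0712	111.1367
FCC4h	50.0729	23.0712	111.1367
FFC1h	-15.0096	54.6299	109.9306
FFC2h	15.0096	54.6299	109.9306
P1h	-13.4617	-55.7824	109.3333
P2h	13.4617	-55.7824	109.3333
CPP3h	-43.2116	-42.8273	106.3218
CPP4h	43.2116	-42.8273	106.3218
FC3h	-47.2752	39.6386	105.5274
FC4h	47.2752	39.6386	105.5274
P1	-26.3232	-55.8982	105.4406
P2	26.3232	-55.8982	105.4406
FFC1	-29.3892	54.7713	105.0875
FFC2	29.3892	54.7713	105.0875
CCP3	-64.0793	-12.0974	102.0282
CCP4	64.0793	-12.0974	102.0282
C3	-65.0465	4.8712	102.0098
C4	65.0465	4.8712	102.0098
CP3	-60.5181	-28.4500	100.2342
CP4	60.5181	-28.4500	100.2342
FCC3	-64.0996	22.2566	99.1260
FCC4	64.0996	22.2566	99.1260
P3h	-38.3233	-56.2786	98.8561
P4h	38.3233	-56.2786	98.8561
F1h	-13.2647	67.5588	97.9643
F2h	13.2647	67.5588	97.9643
PPO1h	-11.5220	-67.8131	98.0398
PPO2h	11.5220	-67.8131	98.0398
FFC3h	-42.8743	54.5472	97.3271
FFC4h	42.8743	54.5472	97.3271
CPP3	-55.3363	-43.2473	96.2811
CPP4	55.3363	-43.2473	96.2811
PPO1	-22.6955	-67.5886	94.9244
PPO2	22.6955	-67.5886	94.9244
FC3	-60.4767	38.9559	94.0833
FC4	60.4767	38.9559	94.0833
F1	-26.0366	67.1288	93.9983
F2	26.0366	67.1288	93.9983
P3	-49.0893	-56.4165	90.0742
P4	49.0893	-56.4165	90.0742
PPO3h	-32.9886	-67.5312	89.5104
PPO4h	32.9886	-67.5312	89.5104
CCP5h	-75.5341	-12.7649	87.2405
CCP6h	75.5341	-12.7649	87.2405
F3h	-37.8031	66.5412	87.3624
F4h	37.8031	66.5412	87.3624
C5h	-76.6422	4.0354	87.0074
C6h	76.6422	4.0354	87.0074
FFC3	-54.8931	53.7206	86.9131
FFC4	54.8931	53.7206	86.9131
CP5h	-71.6063	-29.0113	86.1615
CP6h	71.6063	-29.0113	86.1615
AFF1h	-11.0722	77.5074	84.3848
AFF2h	11.0722	77.5074	84.3848
FCC5h	-75.4918	20.9474	84.2967
FCC6h	75.4918	20.9474	84.2967
PO1h	-8.9725	-78.0183	83.9617
PO2h	8.9725	-78.0183	83.9617
CPP5h	-65.4075	-43.7641	83.6642
CPP6h	65.4075	-43.7641	83.6642
PPO3	-42.1512	-67.3790	82.2296
PPO4	42.1512	-67.3790	82.2296
PO1	-17.6781	-77.8601	81.5366
PO2	17.6781	-77.8601	81.5366
AFF1	-21.8269	76.8100	81.5189
AFF2	21.8269	76.8100	81.5189
FC5h	-71.4645	37.2490	80.0667
FC6h	71.4645	37.2490	80.0667
P5h	-57.9868	-56.6537	79.0883
P6h	57.9868	-56.6537	79.0883
PO3h	-25.7935	-77.5322	77.7287
PO4h	25.7935	-77.5322	77.7287
F3	-48.0203	65.7969	78.2729
F4	48.0203	65.7969	78.2729
AFF3h	-31.5683	76.1218	76.1788
AFF4h	31.5683	76.1218	76.1788
FFC5h	-64.8240	52.2452	74.1801
FFC6h	64.8240	52.2452	74.1801
PPO5h	-49.6795	-67.2733	73.2604
PPO6h	49.6795	-67.2733	73.2604
PO3	-33.3213	-76.9459	72.6959
PO4	33.3213	-76.9459	72.6959
AF1h	-8.5681	84.4286	69.9733
AF2h	8.5681	84.4286	69.9733
CCP5	-83.7450	-13.6627	70.0019
CCP6	83.7450	-13.6627	70.0019
CP5	-79.7213	-29.4582	69.6095
CP6	79.7213	-29.4582	69.6095
C5	-84.9922	3.0714	69.4430
C6	84.9922	3.0714	69.4430
AFF3	-40.0874	75.2063	68.9313
AFF4	40.0874	75.2063	68.9313
CPP5	-72.9512	-44.1672	68.7643
CPP6	72.9512	-44.1672	68.7643
POO1h	-6.2784	-85.0831	68.6609
POO2h	6.2784	-85.0831	68.6609
AF1	-16.6849	83.9471	67.8298
AF2	16.6849	83.9471	67.8298
POO1	-12.4207	-84.5410	68.2587
POO2	12.4207	-84.5410	68.2587
FCC5	-83.4112	19.9668	67.2744
FCC6	83.4112	19.9668	67.2744
F5h	-56.5342	64.4849	67.3053
F6h	56.5342	64.4849	67.3053
PO5h	-39.7774	-76.2854	66.4252
PO6h	39.7774	-76.2854	66.4252
AFp1	-11.1434	88.4981	51.9962
AFp2	11.1434	88.4981	51.9962
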