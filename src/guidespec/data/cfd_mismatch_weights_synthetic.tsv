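position	guide_base	target_base	weight
1	A	C	0.9
1	A	G	0.55
1	A	T	0.7
1	C	A	0.8
1	C	G	0.5
1	C	T	0.85
1	G	A	0.6
1	G	C	0.45
1	G	T	0.95
1	T	A	0.65
1	T	C	0.75
1	T	G	0.88
2	A	C	0.8597
2	A	G	0.5254
2	A	T	0.6687
2	C	A	0.7642
2	C	G	0.4776
2	C	T	0.812
2	G	A	0.5732
2	G	C	0.4299
2	G	T	0.9075
2	T	A	0.6209
2	T	C	0.7164
2	T	G	0.8406
3	A	C	0.8195
3	A	G	0.5008
3	A	T	0.6374
3	C	A	0.7284
3	C	G	0.4553
3	C	T	0.7739
3	G	A	0.5463
3	G	C	0.4097
3	G	T	0.865
3	T	A	0.5918
3	T	C	0.6829
3	T	G	0.8013
4	A	C	0.7792
4	A	G	0.4762
4	A	T	0.6061
4	C	A	0.6926
4	C	G	0.4329
4	C	T	0.7359
4	G	A	0.5195
4	G	C	0.3896
4	G	T	0.8225
4	T	A	0.5628
4	T	C	0.6493
4	T	G	0.7619
5	A	C	0.7389
5	A	G	0.4516
5	A	T	0.5747
5	C	A	0.6568
5	C	G	0.4105
5	C	T	0.6979
5	G	A	0.4926
5	G	C	0.3695
5	G	T	0.78
5	T	A	0.5337
5	T	C	0.6158
5	T	G	0.7225
6	A	C	0.6987
6	A	G	0.427
6	A	T	0.5434
6	C	A	0.6211
6	C	G	0.3882
6	C	T	0.6599
6	G	A	0.4658
6	G	C	0.3493
6	G	T	0.7375
6	T	A	0.5046
6	T	C	0.5822
6	T	G	0.6832
7	A	C	0.6584
7	A	G	0.4024
7	A	T	0.5121
7	C	A	0.5853
7	C	G	0.3658
7	C	T	0.6218
7	G	A	0.4389
7	G	C	0.3292
7	G	T	0.695
7	T	A	0.4755
7	T	C	0.5487
7	T	G	0.6438
8	A	C	0.6182
8	A	G	0.3778
8	A	T	0.4808
8	C	A	0.5495
8	C	G	0.3434
8	C	T	0.5838
8	G	A	0.4121
8	G	C	0.3091
8	G	T	0.6525
8	T	A	0.4464
8	T	C	0.5151
8	T	G	0.6044
9	A	C	0.5779
9	A	G	0.3532
9	A	T	0.4495
9	C	A	0.5137
9	C	G	0.3211
9	C	T	0.5458
9	G	A	0.3853
9	G	C	0.2889
9	G	T	0.61
9	T	A	0.4174
9	T	C	0.4816
9	T	G	0.5651
10	A	C	0.5376
10	A	G	0.3286
10	A	T	0.4182
10	C	A	0.4779
10	C	G	0.2987
10	C	T	0.5078
10	G	A	0.3584
10	G	C	0.2688
10	G	T	0.5675
10	T	A	0.3883
10	T	C	0.448
10	T	G	0.5257
11	A	C	0.4974
11	A	G	0.3039
11	A	T	0.3868
11	C	A	0.4421
11	C	G	0.2763
11	C	T	0.4697
11	G	A	0.3316
11	G	C	0.2487
11	G	T	0.525
11	T	A	0.3592
11	T	C	0.4145
11	T	G	0.4863
12	A	C	0.4571
12	A	G	0.2793
12	A	T	0.3555
12	C	A	0.4063
12	C	G	0.2539
12	C	T	0.4317
12	G	A	0.3047
12	G	C	0.2286
12	G	T	0.4825
12	T	A	0.3301
12	T	C	0.3809
12	T	G	0.4469
13	A	C	0.4168
13	A	G	0.2547
13	A	T	0.3242
13	C	A	0.3705
13	C	G	0.2316
13	C	T	0.3937
13	G	A	0.2779
13	G	C	0.2084
13	G	T	0.44
13	T	A	0.3011
13	T	C	0.3474
13	T	G	0.4076
14	A	C	0.3766
14	A	G	0.2301
14	A	T	0.2929
14	C	A	0.3347
14	C	G	0.2092
14	C	T	0.3557
14	G	A	0.2511
14	G	C	0.1883
14	G	T	0.3975
14	T	A	0.272
14	T	C	0.3138
14	T	G	0.3682
15	A	C	0.3363
15	A	G	0.2055
15	A	T	0.2616
15	C	A	0.2989
15	C	G	0.1868
15	C	T	0.3176
15	G	A	0.2242
15	G	C	0.1682
15	G	T	0.355
15	T	A	0.2429
15	T	C	0.2803
15	T	G	0.3288
16	A	C	0.2961
16	A	G	0.1809
16	A	T	0.2303
16	C	A	0.2632
16	C	G	0.1645
16	C	T	0.2796
16	G	A	0.1974
16	G	C	0.148
16	G	T	0.3125
16	T	A	0.2138
16	T	C	0.2467
16	T	G	0.2895
17	A	C	0.2558
17	A	G	0.1563
17	A	T	0.1989
17	C	A	0.2274
17	C	G	0.1421
17	C	T	0.2416
17	G	A	0.1705
17	G	C	0.1279
17	G	T	0.27
17	T	A	0.1847
17	T	C	0.2132
17	T	G	0.2501
18	A	C	0.2155
18	A	G	0.1317
18	A	T	0.1676
18	C	A	0.1916
18	C	G	0.1197
18	C	T	0.2036
18	G	A	0.1437
18	G	C	0.1078
18	G	T	0.2275
18	T	A	0.1557
18	T	C	0.1796
18	T	G	0.2107
19	A	C	0.1753
19	A	G	0.1071
19	A	T	0.1363
19	C	A	0.1558
19	C	G	0.0974
19	C	T	0.1655
19	G	A	0.1168
19	G	C	0.0876
19	G	T	0.185
19	T	A	0.1266
19	T	C	0.1461
19	T	G	0.1714
20	A	C	0.135
20	A	G	0.0825
20	A	T	0.105
20	C	A	0.12
20	C	G	0.075
20	C	T	0.1275
20	G	A	0.09
20	G	C	0.0675
20	G	T	0.1425
20	T	A	0.0975
20	T	C	0.1125
20	T	G	0.132
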