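# Incoherent (inelastic) atomic scattering function S(q), sampled on q nodes (1/Angstrom).
# Values generated from the Heisenberg-type closure S(q) = Z - f(q)^2/Z with the
# Cromer-Mann elastic factors of this package; geometry-independent, so any small
# deviation from published tabulations is common to model and reference intensities
# and largely cancels in the percent-difference signal. Replaceable by user tables.
q	H	C	N	O	S
0.00	0.000256	0.001600	0.010796	0.001200	0.000400
0.25	0.017490	0.083213	0.081565	0.066161	0.169116
0.50	0.067043	0.318616	0.288095	0.256634	0.656334
0.75	0.142968	0.681655	0.613958	0.559994	1.409619
1.00	0.236867	1.135168	1.034568	0.957092	2.354496
1.25	0.339605	1.638323	1.520701	1.424668	3.409098
1.50	0.442880	2.153364	2.042258	1.938004	4.497567
1.75	0.540269	2.650218	2.571587	2.473365	5.559073
2.00	0.627628	3.108390	3.085835	3.009869	6.551506
2.25	0.702947	3.516573	3.568142	3.530626	7.450710
2.50	0.765887	3.870866	4.007770	4.023162	8.247056
2.75	0.817212	4.172497	4.399422	4.479250	8.941127
3.00	0.858281	4.425730	4.742107	4.894360	9.539738
3.25	0.890670	4.636246	5.037873	5.266908	10.052890
3.50	0.915932	4.810076	5.290632	5.597484	10.491727
3.75	0.935472	4.952982	5.505202	5.888150	10.867324
4.00	0.950492	5.070165	5.686622	6.141863	11.190045
4.25	0.961987	5.166155	5.839713	6.362037	11.469258
4.50	0.970759	5.244820	5.968837	6.552238	11.713214
4.75	0.977446	5.309413	6.077797	6.715972	11.929033
5.00	0.982543	5.362642	6.169839	6.856563	12.122729
5.25	0.986436	5.406741	6.247688	6.977075	12.299264
5.50	0.989416	5.443538	6.313624	7.080280	12.462627
5.75	0.991707	5.474518	6.369551	7.168650	12.615931
6.00	0.993474	5.500880	6.417060	7.244356	12.761529
6.25	0.994843	5.523586	6.457492	7.309292	12.901127
6.50	0.995909	5.543400	6.491977	7.365091	13.035909
6.75	0.996743	5.560931	6.521477	7.413152	13.166649
7.00	0.997396	5.576659	6.546808	7.454666	13.293809
7.25	0.997911	5.590963	6.568668	7.490643	13.417629
7.50	0.998318	5.604141	6.587650	7.521935	13.538195
7.75	0.998640	5.616428	6.604258	7.549259	13.655492
8.00	0.998896	5.628009	6.618920	7.573219	13.769448
8.25	0.999100	5.639027	6.631995	7.594322	13.879964
8.50	0.999263	5.649595	6.643785	7.612995	13.986930
8.75	0.999394	5.659800	6.654541	7.629598	14.090244
9.00	0.999499	5.669709	6.664469	7.644436	14.189819
9.25	0.999584	5.679374	6.673736	7.657767	14.285585
9.50	0.999653	5.688832	6.682480	7.669811	14.377495
9.75	0.999710	5.698111	6.690809	7.680754	14.465524
10.00	0.999756	5.707230	6.698807	7.690758	14.549668
10.25	0.999794	5.716203	6.706542	7.699960	14.629945
10.50	0.999826	5.725036	6.714063	7.708477	14.706392
10.75	0.999852	5.733733	6.721409	7.716412	14.779061
11.00	0.999874	5.742297	6.728607	7.723849	14.848023
11.25	0.999892	5.750724	6.735677	7.730865	14.913360
11.50	0.999908	5.759013	6.742633	7.737522	14.975168
11.75	0.999921	5.767161	6.749482	7.743875	15.033550
12.00	0.999932	5.775161	6.756231	7.749969	15.088621
12.25	0.999942	5.783011	6.762882	7.755843	15.140499
12.50	0.999950	5.790705	6.769435	7.761529	15.189308
12.75	0.999957	5.798240	6.775890	7.767054	15.235177
13.00	0.999963	5.805610	6.782245	7.772440	15.278236
13.25	0.999968	5.812812	6.788499	7.777705	15.318616
13.50	0.999972	5.819842	6.794648	7.782863	15.356447
13.75	0.999976	5.826698	6.800691	7.787926	15.391862
14.00	0.999979	5.833377	6.806626	7.792903	15.424987
14.25	0.999982	5.839877	6.812449	7.797801	15.455949
14.50	0.999984	5.846197	6.818159	7.802625	15.484871
14.75	0.999986	5.852335	6.823754	7.807378	15.511873
15.00	0.999988	5.858292	6.829233	7.812064	15.537070
15.25	0.999989	5.864066	6.834594	7.816684	15.560572
15.50	0.999991	5.869659	6.839836	7.821239	15.582488
15.75	0.999992	5.875070	6.844959	7.825729	15.602918
16.00	0.999993	5.880302	6.849962	7.830153	15.621961
16.25	0.999993	5.885356	6.854845	7.834513	15.639709
16.50	0.999994	5.890233	6.859607	7.838807	15.656249
16.75	0.999995	5.894936	6.864250	7.843033	15.671664
17.00	0.999995	5.899467	6.868773	7.847192	15.686033
17.25	0.999996	5.903830	6.873178	7.851283	15.699429
17.50	0.999996	5.908026	6.877465	7.855304	15.711922
17.75	0.999996	5.912059	6.881635	7.859255	15.723575
18.00	0.999997	5.915933	6.885689	7.863134	15.734452
18.25	0.999997	5.919651	6.889630	7.866941	15.744607
18.50	0.999997	5.923216	6.893457	7.870676	15.754094
18.75	0.999997	5.926633	6.897174	7.874337	15.762963
19.00	0.999997	5.929906	6.900782	7.877925	15.771259
19.25	0.999997	5.933038	6.904282	7.881438	15.779027
19.50	0.999998	5.936034	6.907677	7.884877	15.786304
19.75	0.999998	5.938897	6.910969	7.888241	15.793129
20.00	0.999998	5.941632	6.914160	7.891530	15.799535
20.25	0.999998	5.944243	6.917252	7.894745	15.805555
20.50	0.999998	5.946735	6.920247	7.897884	15.811217
20.75	0.999998	5.949110	6.923148	7.900949	15.816549
21.00	0.999998	5.951374	6.925956	7.903940	15.821577
21.25	0.999998	5.953531	6.928675	7.906857	15.826322
21.50	0.999998	5.955584	6.931307	7.909701	15.830807
21.75	0.999998	5.957538	6.933853	7.912472	15.835052
22.00	0.999998	5.959396	6.936317	7.915170	15.839074
22.25	0.999998	5.961163	6.938700	7.917797	15.842891
22.50	0.999998	5.962841	6.941005	7.920353	15.846517
22.75	0.999998	5.964436	6.943235	7.922839	15.849967
23.00	0.999998	5.965950	6.945391	7.925256	15.853254
23.25	0.999998	5.967387	6.947476	7.927604	15.856390
23.50	0.999998	5.968751	6.949492	7.929885	15.859386
23.75	0.999998	5.970044	6.951441	7.932100	15.862252
24.00	0.999998	5.971270	6.953326	7.934250	15.864997
24.25	0.999998	5.972432	6.955148	7.936335	15.867630
24.50	0.999998	5.973534	6.956910	7.938358	15.870158
24.75	0.999998	5.974577	6.958614	7.940319	15.872589
25.00	0.999998	5.975565	6.960261	7.942218	15.874929
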