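index	food_type	food_code	consumption_frequency
1	Yeast breads	51000100	8275
2	Cookies	53201000	3591
3	Tomatoes	74101000	3468
4	Sandwich	27500050	3297
5	French fries	71400990	3111
6	Soup	58400000	3002
7	Bananas	63107010	2737
8	Tortilla and Corn Chips	54401075	2504
9	Pizza	58106230	2325
10	Tortillas	52215000	1923
11	Apple	63101000	1912
12	Ice cream	13110000	1909
13	White and Brown Rice	56205000	1812
14	Pasta mixed dishes	58146210	1794
15	Mashed potatoes	71501000	1730
16	Breaded fish	26100140	1694
17	Steak	21001000	1693
18	Yogurt	11400000	1326
19	Cakes or cupcakes	53100100	1173
20	Burgers	27510155	1082
21	Chicken breast	24120120	1030
22	Carrots	73101010	1026
23	Melons	63109010	962
24	Pancakes	55100005	854
25	Corn	75216120	802
26	Strawberries	63223020	771
27	Bacon	22600200	742
28	Macaroni or noodles with cheese	58145110	718
29	Whole chicken	24100000	681
30	Doughnuts	53520000	634
31	Avocado	63105010	589
32	Green beans	75205030	575
33	Chicken wing	24160110	562
34	Omelet	32129990	555
35	Pies	53300100	487
36	Pork chop	22101000	470
37	Taco or tostada	58101320	470
38	Fried rice	58150310	465
39	Boiled egg	31103010	454
40	Frankfurter sandwich	27564000	429
41	Burrito	58100160	413
42	Shrimp	26319110	409
43	Fried egg	31105005	408
44	Cinnamon buns	51160110	405
45	Blueberries	63203010	393
46	Muffins	52301000	342
47	Hash browns	71404000	317
48	Meat loaf	27214100	316
49	Pork rib	22701000	315
50	Bagels	51180010	313
51	Brownies	53204000	308
52	Chicken thigh	24150210	302
53	Guacamole	63409010	284
54	Quick breads	52403000	251
55	Chicken tender	24198739	230
56	Tuna salad	27450060	223
57	Baked potato	71100100	219
58	Almonds	42100100	213
59	Waffles	55200010	205
60	Chicken nugget	24198729	199
61	Broccoli	72201100	183
62	Quesadilla	58104710	182
63	Croissants	51166000	178
64	Lasagna	58130011	175
65	Nachos	58104180	157
66	Coleslaw	75141000	143
67	Beans	41100990	135
68	Stew beef	27211200	133
69	French toast	55300010	113
70	Sushi	58151100	95
71	Apple sauce	63101110	93
72	Cabbage	75105000	82
73	Biscuits	52101000	54
74	Grilled salmon	26137110	39
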