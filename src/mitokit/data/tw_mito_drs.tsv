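ID	Repeat Length	Repeat Type	Start1	End1	Start2	End2
DRS1	9875	F	565608	575482	605947	615821
DRS2	5937	F	213806	219742	471391	477327
DRS3	5600	F	86898	92497	141628	147227
DRS4	5483	P	237164	242646	319662	314180
DRS5	1728	P	529058	530785	550700	548973
DRS6	388	P	250458	250845	593826	593439
DRS7	295	F	289376	289670	341859	342153
DRS8	288	F	260811	261098	301192	301479
DRS9	241	P	73190	73430	252355	252115
DRS10	225	P	380076	380300	455856	455632
DRS11	200	F	338753	338952	536718	536917
DRS12	165	F	523613	523777	552149	552313
DRS13	138	F	444909	445046	682863	683000
DRS14	130	F	11917	12046	197372	197501
DRS15	125	F	19468	19592	163717	163841
DRS16	120	P	409541	409422	250339	250458
DRS17	111	F	503030	503140	716487	716377
DRS18	106	F	362472	362577	394369	394474
DRS19	101	F	159986	160086	700671	700771
DRS20	98	P	227118	227215	716057	715960
DRS21	85	P	701099	701115	300221	300305
DRS22	85	F	162454	162538	413199	413283
DRS23	73	P	553929	554001	586127	586055
DRS24	73	P	226954	227026	716254	716182
DRS25	73	P	61726	61798	590179	590107
DRS26	71	F	410796	410866	700746	700816
DRS27	70	F	248538	248607	482163	482232
DRS28	70	P	244244	244313	576606	576537
DRS29	67	F	87186	87252	141916	141982
DRS30	67	F	87186	87252	339733	339799
DRS31	67	F	141916	141982	339733	339799
DRS32	65	P	195478	195542	657450	657386
DRS33	64	F	91720	91783	146450	146513
DRS34	64	F	91720	91783	179993	180056
DRS35	64	F	146450	146513	179993	180056
DRS36	63	F	182246	182308	216152	216214
DRS37	63	F	182246	182308	473737	473799
DRS38	63	F	216152	216214	473737	473799
DRS39	61	P	291156	291216	504253	504193
DRS40	61	F	57622	57682	306075	306135
DRS41	59	F	495093	495151	528531	528589
DRS42	58	F	47031	47088	693744	693801
DRS43	55	P	167131	167185	710277	710223
DRS44	53	F	195516	195568	312661	312713
DRS45	51	F	244667	244717	576983	577033
DRS46	50	P	442609	442560	248466	248515
DRS47	50	P	226067	226116	441070	441021
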