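species	rpoB-trnD	trnD-trnY	ndhC-trnV	psbE-petL	rps12-rrn16	rps15-ycf1	cpdna_size
Adiantum aleuticum	932	110	402	2566	4785*	305	157519
Adiantum capillus-veneris	944	114	487	401	600	290	150568
Adiantum flabellulatum	935	114	380	749	1593	289	152063
Adiantum malesianum	6877*	116	447	-	1265	295	154671
Adiantum nelumboides	833	124	433	-	1260	292	149956
Adiantum reniforme var. sinense	669	124	433	-	1270	292	150102
Adiantum shastense	929	119	402	568	1584	293	150414
Adiantum tricholepis	878	110	405	765	1378	286	150470
Antrophyum semicostatum	7061*	92	-	664	-	279	150274
Haplopteris elongata	944	87	419	797	-	232	156002
Scoliosorus ensiformis	901	99	-	757	-	208	145327
Vaginularia trichoidea	6880*	90	-	537	1200	211	147102
Vittaria appalachiana	3067*	95	-	723	-	201	149531
Vittaria graminifolia	4817*	72	-	735	-	183	151035
Gastoniella chaerophylla	826	99	360	751	1301	209	148099
Onychium japonicum	820	106	379	807	3221*	332	150156
Pityrogramma trifoliata	831	108	394	751	1237	273	148156
Pteris arisanensis	779	105	493	747	7391*	320	160191
Pteris ensiformis	778	105	461	700	1923	321	148985
Pteris multifida	773	111	518	744	4076*	325	153916
Pteris semipinnata	783	105	498	873	8272*	321	162270
Pteris vittata	826	106	454	776	3549*	243	154106
Taenitis blechnoides	7346*	113	530	766	2617	310	157301
Tryonia myriophylla	584	6943*	493	750	2564	294	156327
Acrostichum speciosum	443	116	3953*	503	3730*	-	156095
Ceratopteris cornuta	879	134	1984*	492	1684	322	149424
Ceratopteris thalictroides	886	133	1984*	491	1683	322	149399
Coniogramme intermedia	2593*	105	393	725	1590	305	153561
Cryptogramma acrostichoides	744	105	397	741	1241	306	150162
Llavea cordifolia	818	103	416	721	1563	229	149387
Bommeria hispida	793	118	447	765	1581	6872*	156749
Calciphilopteris ludens	846	119	416	752	4874*	301	157068
Cheilanthes micropteris	875	109	4760*	722	1568	199	157257
Hemionitis subcordata	851	119	422	758	9179*	304	165631
Myriopteris covillei	858	125	440	765	1570	306	155548
Myriopteris lindheimeri	865	121	453	769	1567	306	155770
Myriopteris scabra	849	122	438	761	5336*	3877*	162051
Notholaena standleyi	863	113	445	751	6635*	199	159556
Paragymnopteris bipinnata var. bipinnata	862	133	-	771	1565	303	150736
Pellaea truncata	862	124	461	694	1567	305	150713
Pentagramma triangularis	908	114	443	3890*	1558	194	153445
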