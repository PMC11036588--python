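subfamily	species	size_bp	gc_percent	lsc_bp	ir_bp	ssc_bp	accession
Vittarioideae	Adiantum aleuticum	157519	45.3	82785	53138	21596	NC_040209.1
Vittarioideae	Adiantum capillus-veneris	150568	42.0	82282	46894	21392	NC_004766.1
Vittarioideae	Adiantum flabellulatum	152063	43.3	83384	47230	21449	NC_064144.1
Vittarioideae	Adiantum malesianum	154671	42.6	89030	44154	21487	NC_063331.1
Vittarioideae	Adiantum nelumboides	149956	42.8	83281	45192	21483	NC_050350.1
Vittarioideae	Adiantum reniforme var. sinense	150102	42.8	83267	45376	21459	NC_062433.1
Vittarioideae	Adiantum shastense	150414	44.3	82113	46762	21539	NC_037478.1
Vittarioideae	Adiantum tricholepis	150470	42.5	82606	46403	21461	NC_040172.1
Vittarioideae	Antrophyum semicostatum	150274	40.1	87392	42054	20828	NC_040176.1
Vittarioideae	Haplopteris elongata	156002	40.1	80810	54376	20816	NC_040215.1
Vittarioideae	Scoliosorus ensiformis	145327	40.0	82358	42156	20813	NC_040218.1
Vittarioideae	Vaginularia trichoidea	147102	39.2	84017	43155	19930	NC_040175.1
Vittarioideae	Vittaria appalachiana	149531	40.1	84330	44370	20831	NC_040219.1
Vittarioideae	Vittaria graminifolia	151035	40.1	86058	44132	20845	NC_040217.1
Pteridoideae	Gastoniella chaerophylla	148099	40.3	81915	44646	21538	NC_040210.1
Pteridoideae	Onychium japonicum	150156	41.2	82290	46838	21028	NC_040205.1
Pteridoideae	Pityrogramma trifoliata	148156	40.0	82321	44930	20905	NC_040207.1
Pteridoideae	Pteris arisanensis	160191	42.4	81989	57086	21116	NC_083994.1
Pteridoideae	Pteris ensiformis	148985	41.7	81778	46094	21113	NC_083995.1
Pteridoideae	Pteris multifida	153916	42.2	82027	50760	21129	NC_058883.1
Pteridoideae	Pteris semipinnata	162270	42.3	81963	59182	21125	NC_060734.1
Pteridoideae	Pteris vittata	154106	41.7	82602	50550	20954	MH173082.1
Pteridoideae	Taenitis blechnoides	157301	40.4	88369	47996	20936	NC_083996.1
Pteridoideae	Tryonia myriophylla	156327	40.0	87296	48224	20807	NC_040208.1
Parkerioideae	Acrostichum speciosum	156095	38.4	84476	49734	21885	NC_053768.1
Parkerioideae	Ceratopteris cornuta	149424	36.7	83623	44574	21227	MH173068.1
Parkerioideae	Ceratopteris thalictroides	149399	36.7	83580	44577	21241	NC_062137.1
Cryptogrammoideae	Coniogramme intermedia	153561	45.0	82817	49508	21236	NC_057002.1
Cryptogrammoideae	Cryptogramma acrostichoides	150162	42.3	83763	45231	21168	NC_040211.1
Cryptogrammoideae	Llavea cordifolia	149387	41.9	81944	46416	21027	NC_040216.1
Cheilanthoideae	Bommeria hispida	156749	42.6	82491	46284	27974	NC_040206.1
Cheilanthoideae	Calciphilopteris ludens	157068	43.5	82423	53170	21475	NC_040214.1
Cheilanthoideae	Cheilanthes micropteris	157257	41.4	88145	46550	22562	NC_040174.1
Cheilanthoideae	Hemionitis subcordata	165631	42.8	82607	61842	21182	NC_040173.1
Cheilanthoideae	Myriopteris covillei	155548	42.7	83079	51148	21321	NC_039724.1
Cheilanthoideae	Myriopteris lindheimeri	155770	42.7	83059	51388	21323	NC_014592.1
Cheilanthoideae	Myriopteris scabra	162051	42.1	82874	54230	24947	NC_040213.1
Cheilanthoideae	Notholaena standleyi	159556	42.4	83769	54522	21265	NC_040203.1
Cheilanthoideae	Paragymnopteris bipinnata var. bipinnata	150736	42.5	82926	46516	21294	NC_061171.1
Cheilanthoideae	Pellaea truncata	150713	42.5	82865	46480	21368	NC_040202.1
Cheilanthoideae	Pentagramma triangularis	153445	41.8	85668	46763	21014	NC_040171.1
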