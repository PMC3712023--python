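Gene Symbol	Significance	Chr	Start	End	Region size(bp)
Adsl	3.78655048468349e-14	7	119221149	119221875	726
Arfip1	1.25959624484326e-08	2	176355108	176356091	983
Arl9	3.51696997190646e-16	14	33460390	33461186	796
Bglap	1.52971909876422e-11	2	180484919	180487344	2425
Cst3	1.9676677569316e-05	3	137654243	137654843	600
Dstn	1.8037968573233e-17	3	132358362	132359174	812
Ift80	4.29141490491877e-06	2	158985833	158986919	1086
Il13ra1	1.64249772706228e-06	X	8820511	8821111	600
LOC499584	1.89613932385601e-09	2	110357837	110358437	600
Lyz2	1.07459600381755e-07	7	56612889	56613489	600
Maf	2.18687594147628e-06	19	45861256	45861856	600
Ndor1	1.00275312476137e-12	3	3420722	3421807	1085
Olr111	3.29398302124425e-09	1	161319052	161319652	600
Olr469	6.29429665927461e-07	3	69170933	69171533	600
Pigb	6.9712710596944e-46	8	77794848	77795448	600
Prima1	2.11444223671492e-08	6	127523443	127524268	825
Rab38	6.93621121098414e-07	1	144784135	144785018	883
Sdccag3	5.6108175079916e-06	3	4558626	4559226	600
Sec24a	2.18834047032063e-07	10	37281198	37281798	600
Slco1b3	5.94204976416307e-11	4	179042204	179042804	600
Snrk	4.01338399294972e-07	X	105537519	105538210	691
Sptb	1.24562330248275e-06	6	99316967	99317667	700
Tob2	1.75285493754996e-06	7	120210412	120211293	881
Ube2s	1.1890299638469e-06	1	67742366	67742966	600
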