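HALLMARK_IMMUNE_1	synthetic fixture	G000026	G000033	G000044	G000046	G000049	G000052	G000057	G000058	G000069	G000071	G000075	G000079	G000135	G000146	G000160
HALLMARK_IMMUNE_2	synthetic fixture	G000035	G000036	G000037	G000047	G000073	G000082	G000086	G000090	G000109	G000124	G000135	G000141	G000142	G000147	G000153
HALLMARK_IMMUNE_3	synthetic fixture	G000046	G000056	G000062	G000073	G000080	G000087	G000090	G000091	G000095	G000100	G000110	G000154	G000157	G000159	G000163
HALLMARK_STROMAL_1	synthetic fixture	G000165	G000183	G000195	G000200	G000220	G000236	G000239	G000243	G000248	G000252	G000255	G000278	G000280	G000302	G000303
HALLMARK_STROMAL_2	synthetic fixture	G000172	G000173	G000187	G000193	G000205	G000208	G000219	G000228	G000233	G000234	G000253	G000261	G000262	G000275	G000299
HALLMARK_STROMAL_3	synthetic fixture	G000172	G000175	G000192	G000201	G000212	G000223	G000231	G000248	G000249	G000258	G000261	G000266	G000275	G000279	G000303
HALLMARK_NULL_01	synthetic fixture	G000408	G000619	G000683	G000694	G000801	G000858	G000875	G000880	G000882	G000963	G001087	G001243	G001320	G001490	G001491
HALLMARK_NULL_02	synthetic fixture	G000429	G000446	G000502	G000623	G000665	G000808	G000809	G000876	G000879	G000900	G001074	G001075	G001210	G001292	G001479
HALLMARK_NULL_03	synthetic fixture	G000435	G000473	G000474	G000644	G000791	G000792	G000995	G001032	G001097	G001105	G001112	G001134	G001173	G001197	G001273
HALLMARK_NULL_04	synthetic fixture	G000459	G000491	G000523	G000547	G000577	G000620	G000817	G000983	G001023	G001136	G001218	G001249	G001374	G001458	G001492
HALLMARK_NULL_05	synthetic fixture	G000453	G000479	G000587	G000637	G000671	G000861	G000881	G000951	G000974	G000988	G001023	G001102	G001227	G001312	G001388
HALLMARK_NULL_06	synthetic fixture	G000433	G000450	G000467	G000605	G000606	G000717	G000880	G000943	G000950	G001142	G001145	G001219	G001243	G001417	G001439
HALLMARK_NULL_07	synthetic fixture	G000408	G000475	G000567	G000577	G000593	G000598	G000637	G000665	G000688	G001015	G001130	G001187	G001320	G001368	G001392
HALLMARK_NULL_08	synthetic fixture	G000406	G000634	G000636	G000769	G000782	G000856	G000866	G000889	G001039	G001297	G001331	G001367	G001419	G001466	G001496
HALLMARK_NULL_09	synthetic fixture	G000440	G000536	G000670	G000747	G000788	G000808	G000869	G000879	G000895	G000912	G000931	G001248	G001343	G001456	G001495
HALLMARK_NULL_10	synthetic fixture	G000435	G000436	G000516	G000614	G000636	G000828	G000853	G000899	G000903	G001180	G001329	G001334	G001385	G001386	G001492
HALLMARK_NULL_11	synthetic fixture	G000416	G000508	G000679	G000699	G000740	G000820	G000965	G001069	G001154	G001233	G001274	G001332	G001376	G001402	G001486
HALLMARK_NULL_12	synthetic fixture	G000450	G000518	G000574	G000637	G000652	G000820	G000823	G000970	G000999	G001124	G001218	G001240	G001358	G001362	G001486
HALLMARK_NULL_13	synthetic fixture	G000425	G000494	G000615	G000741	G000849	G000861	G000866	G000923	G000941	G000986	G001001	G001115	G001305	G001325	G001406
HALLMARK_NULL_14	synthetic fixture	G000461	G000579	G000731	G000793	G000816	G000819	G000822	G000848	G000861	G000881	G000966	G000990	G001206	G001278	G001322
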