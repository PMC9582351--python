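CD8_T_effector	synthetic fixture	G000043	G000060	G000064	G000072	G000086	G000093	G000108	G000123	G000128	G000135	G000141	G000144
DNA_damage_repair	synthetic fixture	G000550	G000628	G000676	G000720	G000734	G001079	G001127	G001166	G001171	G001401	G001435	G001457
Antigen_processing_machinery	synthetic fixture	G000035	G000058	G000068	G000081	G000092	G000106	G000113	G000128	G000140	G000145	G000150	G000163
Immune_checkpoint	synthetic fixture	G000031	G000040	G000059	G000067	G000074	G000090	G000097	G000102	G000119	G000130	G000134	G000154
Cell_cycle_regulators	synthetic fixture	G000404	G000445	G000651	G000953	G001098	G001120	G001134	G001165	G001186	G001318	G001349	G001491
Fanconi_anemia	synthetic fixture	G000486	G000516	G000595	G000624	G000638	G000649	G000688	G000911	G000963	G000984	G001166	G001278
Pan_F_TBRS	synthetic fixture	G000179	G000182	G000187	G000191	G000193	G000212	G000232	G000243	G000249	G000272	G000283	G000293
EMT1	synthetic fixture	G000187	G000189	G000203	G000253	G000255	G000256	G000260	G000265	G000285	G000294	G000309	G000312
EMT2	synthetic fixture	G000170	G000174	G000193	G000197	G000216	G000237	G000244	G000258	G000267	G000273	G000294	G000305
EMT3	synthetic fixture	G000173	G000194	G000201	G000225	G000228	G000233	G000242	G000253	G000261	G000282	G000288	G000298
WNT_targets	synthetic fixture	G000439	G000446	G000514	G000540	G000756	G000805	G000859	G000863	G001058	G001356	G001382	G001437
FGFR3_related	synthetic fixture	G000448	G000678	G000850	G000869	G000911	G001005	G001044	G001066	G001069	G001088	G001238	G001494
Cell_cycle	synthetic fixture	G000409	G000474	G000486	G000500	G000525	G000557	G000609	G000909	G000996	G001023	G001241	G001314
Mismatch_repair	synthetic fixture	G000452	G000549	G000600	G000614	G000623	G001075	G001120	G001146	G001179	G001317	G001381	G001440
Homologous_recombination	synthetic fixture	G000595	G000660	G000684	G000690	G000739	G000818	G000857	G000859	G001237	G001282	G001299	G001487
Nucleotide_excision_repair	synthetic fixture	G000410	G000581	G000881	G000899	G000908	G001001	G001027	G001057	G001063	G001150	G001183	G001219
DNA_replication	synthetic fixture	G000414	G000522	G000595	G000654	G000895	G001107	G001152	G001177	G001185	G001323	G001357	G001459
Base_excision_repair	synthetic fixture	G000432	G000646	G000739	G000807	G001013	G001031	G001111	G001142	G001179	G001183	G001194	G001452
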