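sample_id	clean_base_gb	clean_reads	mapped_reads	unique_map_reads	gc_pct	q20_pct	q30_pct
A0-1	16.51	111387804	108051676	96943816	45.88	97.96	94.34
A0-2	16.61	112000780	108910392	97863546	45.7	97.68	93.8
A0-3	16.75	112589572	110609022	100552088	46.04	97.76	93.93
A12-1	16.61	111756856	110089558	101686398	46.27	97.97	94.37
A12-2	17.14	115495834	113230178	103090257	46.64	97.92	94.23
A12-3	16.38	110348698	108489036	99877475	46.31	98	94.45
A48-1	16.09	107944284	106947866	99994308	46.46	97.87	94.22
A48-2	19.38	130001758	128719618	119590397	46.22	97.69	94.03
A48-3	16.43	110257304	109134006	101894550	46.16	97.91	94.32
A72-1	16.96	113843732	112446252	104044056	46.04	97.9	94.27
A72-2	17.56	117850306	116642792	108265039	46.35	97.66	93.79
A72-3	16.30	109961180	107253706	96503806	46.15	97.54	93.79
A120-1	16.64	111668700	109481530	99241207	46.81	97.78	94.01
A120-2	17.98	120868414	118350068	107292896	46.63	97.94	94.3
A120-3	15.96	106992530	105026804	96154578	46.26	98.03	94.53
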