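sample_id	time	event	age	psa	gleason	pt_stage	label
S001	8.9032	1	52.7	8.31	7	pT2b	low
S002	20.8956	1	60.1	3.56	6	pT3b	high
S003	4.9537	1	56.3	24.41	6	pT3a	high
S004	3.1243	1	59.9	4.5	7	pT2a	high
S005	0.713	0	65.9	3.5	7	pT3a	low
S006	11.6364	0	61.3	2.09	6	pT3b	low
S007	26.1916	1	62.2	4.84	7	pT2a	high
S008	30.5658	1	60.7	10.95	7	pT2a	low
S009	1.576	1	70.4	7.41	8	pT3a	high
S010	22.4005	1	61.2	6.53	8	pT2b	low
S011	4.1558	1	63.4	6.35	7	pT3a	low
S012	0.9848	1	62.7	6.91	6	pT2b	low
S013	12.0458	0	59.4	5.6	7	pT2b	low
S014	36.1304	1	57.9	13.23	6	pT3a	low
S015	38.3243	1	57.8	34.7	6	pT2b	low
S016	8.0784	0	59.7	6.26	7	pT2a	low
S017	18.8804	1	61.6	7.37	6	pT2a	high
S018	12.3924	1	61.9	5.63	8	pT2a	low
S019	4.6708	1	67.3	10.7	9	pT3a	high
S020	13.201	1	68.4	10.67	7	pT2a	high
S021	7.4618	1	65.5	10.13	6	pT3a	high
S022	4.6997	1	64.2	5.23	8	pT3b	high
S023	13.5785	0	60.6	5.75	6	pT2b	high
S024	26.979	1	73.7	9.57	6	pT2a	low
S025	0.2265	1	58.8	5.64	7	pT2a	high
S026	3.9167	1	54.8	14.85	7	pT2a	low
S027	25.0716	0	58.6	5.81	7	pT2b	low
S028	3.0079	1	60.5	5.95	6	pT3b	high
S029	6.0161	1	49.1	23.04	9	pT2a	high
S030	6.1036	1	61.7	4.81		pT2b	low
S031	12.8404	1	63.4	11.91	6	pT2b	low
S032	5.1091	1	70.7	17.6	6	pT2b	high
S033	19.1444	1	54.6	6.5	8	pT2a	low
S034	25.3525	1	56.8	12.45	7	pT3a	low
S035	23.4849	0	59.5	4.0	7	pT2b	low
S036	8.0284	1	59.6	22.07	7	pT2a	high
S037	25.739	0	56.3	15.68	7	pT3b	low
S038	1.0841	1	55.8	8.33	7	pT3b	low
S039	2.7236	0	63.3	5.97	6	pT2a	high
S040	27.3259	0	53.2	6.88	6	pT2a	low
S041	4.9383	1	60.0	13.9	8	pT2a	low
S042	23.2754	0	60.2	9.66	7	pT2a	low
S043	15.5581	1	64.6	8.07	9	pT2a	high
S044	17.0251	0	62.9	9.2	7	pT3a	low
S045	17.0254	0	64.3	12.5	6	pT2b	low
S046	6.6434	0	53.3	6.21	6	pT2b	low
S047	4.5521	1	50.3	4.64		pT3b	high
S048	18.3741	1	55.4	27.58	7	pT2a	low
S049	0.4369	1	60.3	16.33	6	pT3b	low
S050	13.0494	0	70.8	9.3	7	pT2a	high
S051	5.7633	1	61.6	9.83	8	pT3a	high
S052	1.6451	1	67.0	20.53	8	pT2b	low
S053	6.661	1	59.9	7.65	6	pT2b	high
S054	10.7171	1	68.1	3.57	9	pT3a	low
S055	5.3166	1	64.8	17.59	6	pT3b	low
S056	18.5483	0	66.3	11.83	7	pT2a	high
S057	11.6971	1	67.7	3.37	7	pT2b	low
S058	0.6886	1	70.6	9.56	7	pT3a	high
S059	0.4792	1	68.6	13.81	6	pT3a	low
S060	17.4572	1	64.7	9.29	6	pT2a	low
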