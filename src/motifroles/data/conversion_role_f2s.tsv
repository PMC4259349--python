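# motifroles conversion matrix; level=role; direction=functional_to_structural; ordering=paper
	role_1	role_2	role_3	role_4	role_5	role_6	role_7	role_8	role_9	role_10	role_11	role_12	role_13	role_14	role_15	role_16	role_17	role_18	role_19	role_20	role_21	role_22	role_23	role_24	role_25	role_26	role_27	role_28	role_29	role_30
role_1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_2	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_3	-1	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_4	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_5	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_6	0	0	0	-1	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_7	-1	0	0	0	-1	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_8	0	-1	0	-1	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_9	1	1	-1	1	1	-1	-1	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_10	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_11	0	0	0	-1	-1	0	0	0	0	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_12	0	0	0	2	2	-2	0	0	0	1	-2	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_13	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_14	-1	-1	0	0	0	0	0	0	0	0	0	0	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_15	2	2	-2	0	0	0	0	0	0	0	0	0	1	-2	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_16	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
role_17	0	-1	0	0	-1	0	0	0	0	0	0	0	0	0	0	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
role_18	-1	0	0	-1	0	0	0	0	0	0	0	0	0	0	0	-1	0	1	0	0	0	0	0	0	0	0	0	0	0	0
role_19	1	1	-1	1	1	-1	0	0	0	0	0	0	0	0	0	1	-1	-1	1	0	0	0	0	0	0	0	0	0	0	0
role_20	0	0	0	0	0	0	0	0	0	0	0	0	-1	0	0	-1	0	0	0	1	0	0	0	0	0	0	0	0	0	0
role_21	1	1	0	0	1	0	-1	0	0	0	0	0	1	-1	0	1	-1	0	0	-1	1	0	0	0	0	0	0	0	0	0
role_22	1	1	0	1	0	0	0	-1	0	0	0	0	1	-1	0	1	0	-1	0	-1	0	1	0	0	0	0	0	0	0	0
role_23	-2	-2	2	-1	-1	1	1	1	-1	0	0	0	-1	2	-1	-1	1	1	-1	1	-1	-1	1	0	0	0	0	0	0	0
role_24	0	0	0	0	0	0	0	0	0	-1	0	0	0	0	0	-1	0	0	0	0	0	0	0	1	0	0	0	0	0	0
role_25	1	0	0	1	1	0	-1	0	0	1	-1	0	0	0	0	1	0	-1	0	0	0	0	0	-1	1	0	0	0	0	0
role_26	0	1	0	1	1	0	0	-1	0	1	-1	0	0	0	0	1	-1	0	0	0	0	0	0	-1	0	1	0	0	0	0
role_27	-1	-1	1	-2	-2	2	1	1	-1	-1	2	-1	0	0	0	-1	1	1	-1	0	0	0	0	1	-1	-1	1	0	0	0
role_28	0	0	0	0	0	0	0	0	0	1	0	0	1	0	0	2	0	0	0	-2	0	0	0	-2	0	0	0	1	0	0
role_29	-1	-1	0	-1	-1	0	1	1	0	-1	1	0	-1	1	0	-2	1	1	0	2	-1	-1	0	2	-1	-1	0	-1	1	0
role_30	2	2	-2	2	2	-2	-2	-2	2	1	-2	1	1	-2	1	2	-2	-2	2	-2	2	2	-2	-2	2	2	-2	1	-2	1
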