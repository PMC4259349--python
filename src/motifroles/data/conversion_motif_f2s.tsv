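# motifroles conversion matrix; level=motif; direction=functional_to_structural; ordering=paper
	motif_1	motif_2	motif_3	motif_4	motif_5	motif_6	motif_7	motif_8	motif_9	motif_10	motif_11	motif_12	motif_13
motif_1	1	0	0	0	0	0	0	0	0	0	0	0	0
motif_2	0	1	0	0	0	0	0	0	0	0	0	0	0
motif_3	0	0	1	0	0	0	0	0	0	0	0	0	0
motif_4	-1	-1	0	1	0	0	0	0	0	0	0	0	0
motif_5	0	-3	0	0	1	0	0	0	0	0	0	0	0
motif_6	0	-1	-1	0	0	1	0	0	0	0	0	0	0
motif_7	2	2	1	-2	0	0	1	0	-2	0	0	0	0
motif_8	1	3	1	-1	-1	-1	0	1	-1	0	0	0	0
motif_9	-1	-1	-1	0	0	0	0	0	1	0	0	0	0
motif_10	1	2	1	-2	0	-2	0	0	0	1	0	0	0
motif_11	1	2	2	0	0	-2	0	0	-2	0	1	0	0
motif_12	-2	-4	-2	3	1	3	-1	-2	3	-1	-1	1	0
motif_13	3	6	3	-6	-2	-6	3	6	-6	3	3	-6	1
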