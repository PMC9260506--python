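clone_name	clone_size	mouse	cdr3_alpha	trav	traj	cdr3_beta	trbv	trbd	trbj
7PPG1	26	AIP 2	CAAKDYSNNRLTL	7-2	7	CASSPPGDTQYF	3	1	2-5
7PPG2	22	AIP 1	CAAKDYSNNRLTL	10	7	CASSPPGGSEVFF	5	1	1-1
7PPG3	12	AIP 3	CAAKDYSNNRLTL	10	7	CASSPPGSQNTLYF	5	1	2-4
7ELG1	9	AIP 2	CAASDYSNNRLTL	7-2	7	CASSLELGGREQYF	16	2	2-7
7PPG4	6	AIP 3	CAAKDYSNNRLTL	10D	7	CASSPPGQNTEVFF	4	1	1-1
7DLG1	3	untr	CAAKDYSNNRLTL	10D	7	CASSQDLGNSDYTF	5	1	1-2
7DLG2	3	AIP 2	CAAKDYSNNRLTL	10D	7	CASSQDLGYAEQFF	5	2	2-1
7AQG1	2	untr	CAASDYSNNRLTL	7-2	7	CASSQAQGGGAEQFF	5	1	2-1
7EGA1	2	AIP 2	CAAKDYSNNRLTL	5D-4	7	CASSQEGANTEVFF	2	1	1-1
7PPG5	1	untr	CAAKDYSNNRLTL	10	7	CASSPPGVNTEVFF	5	1	1-1
7DPG1	1	AIP 1	CAAKDYSNNRLTL	10	7	CASSQDPGGNAEQFF	2	2	2-1
7PPG6	1	AIP 3	CAAKDYSNNRLTL	10	7	CASSPPGGDTEVFF	5	1	1-1
7TPG1	1	AIP 2	CAAKDYSNNRLTL	7-2	7	CASSTPGQNTEVFF	4	1	1-1
7NWS1	1	AIP 2	CAASDYSNNRLTL	7-2	7	CASSLNWSQDTQYF	16	2	2-5
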