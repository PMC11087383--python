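patient	group	rank_in_group	rank_in_activation_group	n_cells	TRAV	TRAJ	CDR3_alpha	TRBV	TRBD	TRBJ	CDR3_beta	norm_IFNG	norm_TNFRSF9	activation_score
P1	IFN	1	3	3	TRAV1-2	TRAJ28	CAVRDQEEYSGAGSYQLTF	TRBV4-3	TRBD1	TRBJ1-6	CASSPGVGEYNSPLHF	1.74	1.08	0.74
P1	IFN	2	19	3	TRAV38-1	TRAJ39	CAFTYMNNNAGNMLTF	TRBV7-6	TRBD2	TRBJ2-1	CASSGPGLAGGEQFF	0.96	0.00	0.42
P1	IFN	3	56	3	TRAV21	TRAJ15	CAAPNQAGTALIF	TRBV7-9	TRBD2	TRBJ2-2	CASSATSGEAGELFF	0.84	0.00	0.09
P1	41BB	1	3	3	TRAV1-2	TRAJ28	CAVRDQEEYSGAGSYQLTF	TRBV4-3	TRBD1	TRBJ1-6	CASSPGVGEYNSPLHF	1.74	1.08	0.74
P1	41BB	2	86	3	TRAV12-2	TRAJ33	CAPMDSNYQLIW	TRBV18	TRBD2	TRBJ2-3	CASSPREGMADTQYF	0.00	0.32	0.00
P1	41BB	3	301	2	TRAV13-1	TRAJ36	CAATDQTGANNLFF	TRBV29-1	None	TRBJ2-1	CSVEVWENEQFF	0.35	0.22	0.30
P1	activation	1	1	3	TRAV21	TRAJ23	CAGHGYNQGGKLIF	TRBV7-9	TRBD2	TRBJ2-5	CASSSTSGGPIQETQYF	0.25	0.00	0.79
P1	activation	2	2	4	TRAV8-4	TRAJ45	CAVSGLSGGGADGLTF	TRBV27	None	TRBJ1-1	CASSLRVNTEAFF	0.00	0.00	0.77
P1	activation	3	3	3	TRAV1-2	TRAJ28	CAVRDQEEYSGAGSYQLTF	TRBV4-3	TRBD1	TRBJ1-6	CASSPGVGEYNSPLHF	1.74	1.08	0.74
P2	IFN	1	5	3	TRAV12-1	TRAJ9	CVVYTGGFKTIF	TRBV20-1	TRBD1	TRBJ2-2	CSASLRGKRGTGELFF	1.94	0.56	0.67
P2	IFN	2	7	4	TRAV35	TRAJ38	CAAHAGNNRKLIW	TRBV7-3	TRBD1	TRBJ2-3	CASSLGGVDTQYF	1.25	0.00	0.60
P2	IFN	3	114	6	TRAV17	TRAJ30	CATVFNRDDKIIF	TRBV5-1	TRBD2	TRBJ1-1	CASSFWDLNTEAFF	1.17	0.00	0.15
P2	41BB	1	5	3	TRAV12-1	TRAJ9	CVVYTGGFKTIF	TRBV20-1	TRBD1	TRBJ2-2	CSASLRGKRGTGELFF	1.94	0.56	0.67
P2	41BB	2	84	7	TRAV12-1	TRAJ41	CVVTNSNSGYALNF	TRBV6-3	TRBD2	TRBJ2-3	CASRSGRRTDTQYF	0.55	0.50	0.21
P2	41BB	3	116	5	TRAV27	TRAJ50	CAGPMKTSYDKVIF	TRBV12-4	None	TRBJ2-7	CASSLNSYEQYF	0.50	0.39	0.15
P2	activation	1	1	3	TRAV8-4	TRAJ6	CAVPRSGGSYIPTF	TRBV28	None	TRBJ2-7	CASSPIPLYGSHEQYF	0.42	0.00	0.83
P2	activation	2	2	4	TRAV35	TRAJ35	CAGQEGGFGNVLHC	TRBV27	TRBD2	TRBJ1-2	CASSERALAGYTF	0.00	0.00	0.76
P2	activation	3	3	6	TRAV41	TRAJ44	CAVDRGTASKLTF	TRBV9	TRBD1	TRBJ2-1	CASRGTGDEQFF	1.15	0.00	0.70
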