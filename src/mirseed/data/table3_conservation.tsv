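mirna_name	sequence	conservation_rate	read_counts
mol-miR166i	UCGGACCAGGCUUCAUUCCCCC	147	65,243
mol-miR156	CUGACAGAAGAGAGUGAGCAC	136	2,459
mol-miR160h	UGCCUGGCUCCCUGUAUGCCAUU	91	25
mol-miR395a	CUGAAGUGUUUGGGGGAACUC	90	84
mol-miR171c-3p	UGAUUGAGCCGUGCCAAUAUC	77	503
mol-miR164d	UGGAGAAGCAGGGCACGUGCA	73	373
mol-miR167b	UGAAGCUGCCAGCAUGAUCUA	66	3,834
mol-miR157a-5p	UUGACAGAAGAUAGAGAGCAC	63	316
mol-miR390a-5p	AAGCUCAGGAGGGAUAGCGCC	54	1,128
mol-miR169d	UAGCCAAGGAUGACUUGCCU	51	22
mol-miR394b-5p	UUGGCAUUCUGUCCACCUCC	44	1,147
mol-miR396c	UUCCACAGCUUUCUUGAACUU	40	7,917
mol-miR167d	UGAAGCUGCCAGCAUGAUCUGA	38	4.007
mol-miR162	UCGAUAAACCUCUGCAUCCAG	34	158
mol-miR319e	UUUGGACUGAAGGGAGCUCCU	33	2,843
mol-miR403	UUAGAUUCACGCACAAACUCG	31	5,277
mol-miR171d	UUGAGCCGUGCCAAUAUCACG	30	410
mol-miR168d-5p	UCGCUUGGUGCAGGUCGGGAA	25	517
mol-miR393b	UCCAAAGGGAUCGCAUUGAUC	24	1,730
mol-miR159a	UUUGGAUUGAAGGGAGCUCUA	23	11,908
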