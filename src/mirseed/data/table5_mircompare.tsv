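human_mirna	plant_mirna	r_value	alignment_pattern
hsa-miR6503-3p	mol-miR166i	0.67	-GGAC-AGG-U-CA--CC-CC
hsa-miR548ah-5p	mol-miR393c	0.65	-AAAG-GAU-GCA-UG-U--
hsa-miR3940-5p	mol-miR159a	0.65	-UGG-UUG--G-G-GCUCU-
hsa-miR579	mol-miR168a	0.57	UC--UUGGU--A---CG-GA-
hsa-miR4534	mol-miR159a	0.71	GGAU-GA-G-G-G-UCU
hsa-miR1306-3p	mol-miR6478	0.78	AC-UU-GCUC-G-UGGUG
hsa-miR4703-3p	mol-miR6300	0.72	GU-GUUGUA-U-UA-UG-
hsa-miR5008-5p	mol-miR6300	0.67	G-C-UUG--G-A-AGUGG
hsa-miR4273	mol-miR398c	0.67	GUGUUCUC-G-U-G-C--
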