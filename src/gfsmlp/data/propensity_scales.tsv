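# Amino-acid propensity scales bundled with gfsmlp (scale_name <TAB> residue <TAB> value).
# Values are in the original literature units; gfsmlp normalises each scale to [-1, 1] before use.
# 1. hydrophilicity_parker  — Parker, Guo & Hodges (1986) HPLC-derived hydrophilicity.
# 2. accessibility_emini    — Emini et al. (1985) surface accessibility probability.
# 3. flexibility_karplus    — Karplus & Schulz (1985) chain flexibility (B-value) parameters.
# 4. surface_janin          — Janin (1979) interior/surface transfer free energy (kcal/mol).
# 5. polarity_ponnuswamy    — residue polarity, standard tabulation (Grantham 1974 values as
#                             reproduced in the epitope-propensity literature).
# 6. turns_pellequer        — turn preference; Levitt (1978) normalised turn frequencies
#                             (alternative tabulation of the Pellequer 1993 turn scale).
# 7. antigenicity_kolaskar  — Kolaskar & Tongaonkar (1990) antigenic propensity.
# 8. beta_turn_chou         — Chou & Fasman (1978) normalised beta-turn frequency.
hydrophilicity_parker	A	2.1
hydrophilicity_parker	C	1.4
hydrophilicity_parker	D	10.0
hydrophilicity_parker	E	7.8
hydrophilicity_parker	F	-9.2
hydrophilicity_parker	G	5.7
hydrophilicity_parker	H	2.1
hydrophilicity_parker	I	-8.0
hydrophilicity_parker	K	5.7
hydrophilicity_parker	L	-9.2
hydrophilicity_parker	M	-4.2
hydrophilicity_parker	N	7.0
hydrophilicity_parker	P	2.1
hydrophilicity_parker	Q	6.0
hydrophilicity_parker	R	4.2
hydrophilicity_parker	S	6.5
hydrophilicity_parker	T	5.2
hydrophilicity_parker	V	-3.7
hydrophilicity_parker	W	-10.0
hydrophilicity_parker	Y	-1.9
accessibility_emini	A	0.815
accessibility_emini	C	0.394
accessibility_emini	D	1.283
accessibility_emini	E	1.445
accessibility_emini	F	0.695
accessibility_emini	G	0.714
accessibility_emini	H	1.180
accessibility_emini	I	0.603
accessibility_emini	K	1.545
accessibility_emini	L	0.603
accessibility_emini	M	0.714
accessibility_emini	N	1.296
accessibility_emini	P	1.236
accessibility_emini	Q	1.348
accessibility_emini	R	1.475
accessibility_emini	S	1.115
accessibility_emini	T	1.184
accessibility_emini	V	0.606
accessibility_emini	W	0.808
accessibility_emini	Y	1.089
flexibility_karplus	A	1.041
flexibility_karplus	C	0.960
flexibility_karplus	D	1.033
flexibility_karplus	E	1.094
flexibility_karplus	F	0.930
flexibility_karplus	G	1.142
flexibility_karplus	H	0.982
flexibility_karplus	I	1.002
flexibility_karplus	K	1.093
flexibility_karplus	L	0.967
flexibility_karplus	M	0.947
flexibility_karplus	N	1.117
flexibility_karplus	P	1.055
flexibility_karplus	Q	1.165
flexibility_karplus	R	1.038
flexibility_karplus	S	1.169
flexibility_karplus	T	1.073
flexibility_karplus	V	0.982
flexibility_karplus	W	0.925
flexibility_karplus	Y	0.961
surface_janin	A	0.3
surface_janin	C	0.9
surface_janin	D	-0.6
surface_janin	E	-0.7
surface_janin	F	0.5
surface_janin	G	0.3
surface_janin	H	-0.1
surface_janin	I	0.7
surface_janin	K	-1.8
surface_janin	L	0.5
surface_janin	M	0.4
surface_janin	N	-0.5
surface_janin	P	-0.3
surface_janin	Q	-0.7
surface_janin	R	-1.4
surface_janin	S	-0.1
surface_janin	T	-0.2
surface_janin	V	0.6
surface_janin	W	0.3
surface_janin	Y	-0.4
polarity_ponnuswamy	A	8.1
polarity_ponnuswamy	C	5.5
polarity_ponnuswamy	D	13.0
polarity_ponnuswamy	E	12.3
polarity_ponnuswamy	F	5.2
polarity_ponnuswamy	G	9.0
polarity_ponnuswamy	H	10.4
polarity_ponnuswamy	I	5.2
polarity_ponnuswamy	K	11.3
polarity_ponnuswamy	L	4.9
polarity_ponnuswamy	M	5.7
polarity_ponnuswamy	N	11.6
polarity_ponnuswamy	P	8.0
polarity_ponnuswamy	Q	10.5
polarity_ponnuswamy	R	10.5
polarity_ponnuswamy	S	9.2
polarity_ponnuswamy	T	8.6
polarity_ponnuswamy	V	5.9
polarity_ponnuswamy	W	5.4
polarity_ponnuswamy	Y	6.2
turns_pellequer	A	0.77
turns_pellequer	C	0.81
turns_pellequer	D	1.41
turns_pellequer	E	0.99
turns_pellequer	F	0.59
turns_pellequer	G	1.64
turns_pellequer	H	0.68
turns_pellequer	I	0.51
turns_pellequer	K	0.96
turns_pellequer	L	0.58
turns_pellequer	M	0.41
turns_pellequer	N	1.28
turns_pellequer	P	1.91
turns_pellequer	Q	0.98
turns_pellequer	R	0.88
turns_pellequer	S	1.32
turns_pellequer	T	1.04
turns_pellequer	V	0.47
turns_pellequer	W	0.76
turns_pellequer	Y	1.05
antigenicity_kolaskar	A	1.064
antigenicity_kolaskar	C	1.412
antigenicity_kolaskar	D	0.866
antigenicity_kolaskar	E	0.851
antigenicity_kolaskar	F	1.091
antigenicity_kolaskar	G	0.874
antigenicity_kolaskar	H	1.105
antigenicity_kolaskar	I	1.152
antigenicity_kolaskar	K	0.930
antigenicity_kolaskar	L	1.250
antigenicity_kolaskar	M	0.826
antigenicity_kolaskar	N	0.776
antigenicity_kolaskar	P	1.064
antigenicity_kolaskar	Q	1.015
antigenicity_kolaskar	R	0.873
antigenicity_kolaskar	S	1.012
antigenicity_kolaskar	T	0.909
antigenicity_kolaskar	V	1.383
antigenicity_kolaskar	W	0.893
antigenicity_kolaskar	Y	1.161
beta_turn_chou	A	0.66
beta_turn_chou	C	1.19
beta_turn_chou	D	1.46
beta_turn_chou	E	0.74
beta_turn_chou	F	0.60
beta_turn_chou	G	1.56
beta_turn_chou	H	0.95
beta_turn_chou	I	0.47
beta_turn_chou	K	1.01
beta_turn_chou	L	0.59
beta_turn_chou	M	0.60
beta_turn_chou	N	1.56
beta_turn_chou	P	1.52
beta_turn_chou	Q	0.98
beta_turn_chou	R	0.95
beta_turn_chou	S	1.43
beta_turn_chou	T	0.96
beta_turn_chou	V	0.50
beta_turn_chou	W	0.96
beta_turn_chou	Y	1.14
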