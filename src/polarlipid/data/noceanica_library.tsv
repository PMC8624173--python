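# Synthetic stand-in library for the N. oceanica polar lipidome.
# Per-class species counts follow the published totals (128 species:
# 15 MGDG, 5 MGMG, 14 DGDG, 2 DGMG, 10 SQDG, 1 SQMG, 19 DGTS, 4 MGTS,
# 11 PG, 6 PI, 10 PE, 20 PC, 9 LPC, 2 PI-Cer).  Species named in the text
# are included verbatim; remaining slots are filled from literature-typical
# Nannochloropsis acyl chains (14:0, 16:0, 16:1, 18:1, 18:2, 18:3, 20:4, 20:5).
# PI-Cer rows give the amide-linked fatty acid; the d18:1 base is implicit.
class_code	chains	sn_resolved
MGDG	14:0_16:0	0
MGDG	14:0_16:1	0
MGDG	16:0_16:1	0
MGDG	16:1_16:1	0
MGDG	16:0_18:1	0
MGDG	16:1_18:3	0
MGDG	20:5/14:0	1
MGDG	18:1_18:2	0
MGDG	20:5/16:0	1
MGDG	20:5/16:1	1
MGDG	18:1_20:5	0
MGDG	18:2_20:5	0
MGDG	18:3_20:5	0
MGDG	20:4_20:5	0
MGDG	20:5/20:5	1
MGMG	14:0	0
MGMG	16:0	0
MGMG	16:1	0
MGMG	18:1	0
MGMG	20:5	0
DGDG	14:0_16:0	0
DGDG	14:0_16:1	0
DGDG	16:0_16:1	0
DGDG	16:1_16:1	0
DGDG	16:0_18:1	0
DGDG	20:5/14:0	1
DGDG	18:1_18:2	0
DGDG	20:5/16:0	1
DGDG	20:5/16:1	1
DGDG	18:1_20:5	0
DGDG	18:2_20:5	0
DGDG	18:3_20:5	0
DGDG	20:4_20:5	0
DGDG	20:5/20:5	1
DGMG	16:1	0
DGMG	16:0	0
SQDG	14:0_14:0	0
SQDG	14:0_16:0	0
SQDG	14:0_16:1	0
SQDG	16:0_16:1	0
SQDG	16:1_16:1	0
SQDG	16:0_18:1	0
SQDG	14:0_20:5	0
SQDG	16:0_20:5	0
SQDG	16:1_20:5	0
SQDG	20:5_20:5	0
SQMG	16:0	0
DGTS	14:0_14:0	0
DGTS	14:0_16:0	0
DGTS	14:0_16:1	0
DGTS	16:0_16:0	0
DGTS	16:0_16:1	0
DGTS	16:1_16:1	0
DGTS	16:0_18:1	0
DGTS	16:1_18:1	0
DGTS	16:1_18:3	0
DGTS	14:0_20:5	0
DGTS	18:1_18:1	0
DGTS	18:1_18:2	0
DGTS	18:2_18:2	0
DGTS	16:0_20:5	0
DGTS	16:1_20:5	0
DGTS	18:1_20:5	0
DGTS	18:2_20:5	0
DGTS	20:4_20:5	0
DGTS	20:5_20:5	0
MGTS	14:0	0
MGTS	16:0	0
MGTS	18:1	0
MGTS	20:5	0
PG	14:0_16:0	0
PG	14:0_16:1	0
PG	16:0_16:0	0
PG	16:0_16:1	0
PG	16:0_18:1	0
PG	16:1_18:1	0
PG	14:0_20:5	0
PG	16:0_20:5	0
PG	16:1_20:5	0
PG	18:1_20:5	0
PG	20:5_20:5	0
PI	14:0_16:0	0
PI	16:0_16:1	0
PI	16:0_18:1	0
PI	16:1_18:1	0
PI	16:0_20:5	0
PI	16:1_20:5	0
PE	14:0_16:0	0
PE	16:0_16:1	0
PE	16:0_18:1	0
PE	16:1_18:1	0
PE	16:0_20:5	0
PE	16:1_20:5	0
PE	18:1_20:5	0
PE	18:2_20:5	0
PE	20:4_20:5	0
PE	20:5_20:5	0
PC	14:0_16:0	0
PC	18:3_20:5	0
PC	14:0_16:1	0
PC	16:0_16:0	0
PC	16:0_16:1	0
PC	16:1_16:1	0
PC	16:0_18:1	0
PC	16:1_18:1	0
PC	16:1_18:3	0
PC	14:0_20:5	0
PC	18:1_18:1	0
PC	18:1_18:2	0
PC	18:1_18:3	0
PC	16:0_20:5	0
PC	16:1_20:5	0
PC	36:7	0
PC	18:1_20:5	0
PC	18:2_20:5	0
PC	20:4_20:5	0
PC	20:5_20:5	0
LPC	14:0	0
LPC	16:0	0
LPC	16:1	0
LPC	16:2	0
LPC	18:1	0
LPC	18:2	0
LPC	18:3	0
LPC	20:4	0
LPC	20:5	0
PI-Cer	16:0	0
PI-Cer	18:1	0
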