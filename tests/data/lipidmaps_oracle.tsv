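name	lipidmaps_abbrev	formula	adduct	mz
MGDG(16:0_18:1)	MGDG(16:0/18:1)	C43H80O10	[M+NH4]+	774.60897
MGDG(20:5_20:5)	MGDG(20:5/20:5)	C49H74O10	[M+NH4]+	840.56202
MGMG(16:0)	MGMG(16:0)	C25H48O9	[M+NH4]+	510.36366
MGMG(20:5)	MGMG(20:5)	C29H46O9	[M+NH4]+	556.34801
DGDG(16:0_18:1)	DGDG(16:0/18:1)	C49H90O15	[M+NH4]+	936.66180
DGDG(20:5_20:5)	DGDG(20:5/20:5)	C55H84O15	[M+NH4]+	1002.61485
DGMG(16:0)	DGMG(16:0)	C31H58O14	[M+NH4]+	672.41648
SQDG(16:0_18:1)	SQDG(16:0/18:1)	C43H80O12S	[M-H]-	819.52977
SQDG(14:0_16:1)	SQDG(14:0/16:1)	C39H72O12S	[M-H]-	763.46717
SQMG(16:0)	SQMG(16:0)	C25H48O11S	[M-H]-	555.28446
DGTS(16:0_18:1)	DGTS(16:0/18:1)	C44H83NO7	[M+H]+	738.62423
DGTS(20:5_20:5)	DGTS(20:5/20:5)	C50H77NO7	[M+H]+	804.57728
MGTS(20:5)	DGTS(20:5/0:0)	C30H49NO6	[M+H]+	520.36326
PC(16:0_18:1)	PC(16:0/18:1)	C42H82NO8P	[M+H]+	760.58508
PC(14:0_14:0)	PC(14:0/14:0)	C36H72NO8P	[M+H]+	678.50683
LPC(16:0)	LPC(16:0)	C24H50NO7P	[M+H]+	496.33977
LPC(19:0)	LPC(19:0)	C27H56NO7P	[M+H]+	538.38672
PE(16:0_18:1)	PE(16:0/18:1)	C39H76NO8P	[M+H]+	718.53813
PE(14:0_14:0)	PE(14:0/14:0)	C33H66NO8P	[M+H]+	636.45988
PG(16:0_18:1)	PG(16:0/18:1)	C40H77O10P	[M-H]-	747.51816
PG(14:0_14:0)	PG(14:0/14:0)	C34H67O10P	[M-H]-	665.43991
PI(16:0_18:1)	PI(16:0/18:1)	C43H81O13P	[M-H]-	835.53420
PI(16:0_16:0)	PI(16:0/16:0)	C41H79O13P	[M-H]-	809.51855
PI-Cer(d34:1)	PI-Cer(d18:1/16:0)	C40H78NO11P	[M-H]-	778.52397
PI-Cer(d36:2)	PI-Cer(d18:1/18:1)	C42H80NO11P	[M-H]-	804.53962
PC(16:0_18:1)	PC(16:0/18:1)	C42H82NO8P	[M+CH3COO]-	818.59166
LPC(16:0)	LPC(16:0)	C24H50NO7P	[M+CH3COO]-	554.34634
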