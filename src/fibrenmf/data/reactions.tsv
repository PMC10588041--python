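aft_id	kind	members	substrate	product	module
AFT_1	KO-pathway	K01809	mannose	F6P	mannose
AFT_2	KO-pathway	K00882	fructose	FBP	fructose
AFT_3	KO-pathway	K06859	glucose	G6P	EMP
AFT_4	KO-pathway	K01810	G6P	F6P	EMP
AFT_5	KO-pathway	K01803	F6P	FBP	EMP
AFT_6	KO-pathway	K00150	FBP	GAP	EMP
AFT_7	KO-pathway	K00134	FBP	GAP	EMP
AFT_8	KO-pathway	K00927	GAP	PG3	EMP
AFT_9	KO-pathway	K00131	KDPG	PG3	SPED
AFT_10	KO-pathway	K01834	PG3	PEP	EMP
AFT_11	KO-pathway	K01689	PEP	PYR	EMP
AFT_12	KO-pathway	K00036	G6P	PGLCN	ED
AFT_13	KO-pathway	K01057	PGLCN	KDPG	ED
AFT_14	KO-pathway	K07404	gluconate	KDG	SPED
AFT_15	KO-pathway	K01690	KDPG	GAP	ED
AFT_16	KO-pathway	K00874	KDG	KDPG	SPED
AFT_17	KO-pathway	K00041	galactose	GAL1P	galactose
AFT_18	KO-pathway	K01685	galacturonate	KDG	pectin_fermentation
AFT_19	KO-pathway	K00883	galactose	PYR	galactose_alt
AFT_20	KO-pathway	K00849	galactose	GAL1P	galactose
AFT_21	KO-pathway	K00965	GAL1P	G6P	galactose
AFT_22	KO-pathway	K01818	fucose	FUCULOSE	fucose
AFT_23	KO-pathway	K00879	FUCULOSE	FUC1P	fucose
AFT_24	KO-pathway	K01628	FUC1P	LACALD	fucose
AFT_25	KO-pathway	K01813	rhamnose	LACALD	rhamnose
AFT_26	KO-pathway	K01804	arabinose	RIB5P	arabinose
AFT_27	KO-pathway	K01786	fructose	F6P	fructose
AFT_28	KO-pathway	K03077	RIB5P	XYL5P	arabinose
AFT_29	KO-pathway	K03080	XYL5P	GAP	pentose
AFT_30	KO-pathway	K00854	xylose	XYL5P	xylose
AFT_31	KO-pathway	K01621	F6P	ACCOA	bif_shunt
AFT_32	KO-pathway	K00169;K00170;K00171;K00172	PYR	ACCOA	pyruvate
AFT_33	KO-pathway	K00627	PYR	ACCOA	pyruvate
AFT_34	KO-pathway	K03737	PYR	ACETOIN	butanediol
AFT_35	KO-pathway	K00656	PYR	ACCOA	pyruvate
AFT_36	KO-pathway	K04020	ACCOA	acetate	acetate_alt
AFT_37	KO-pathway	K00625	ACCOA	ACAC	acetone
AFT_38	KO-pathway	K00925	ACCOA	acetate	acetate
AFT_39	KO-pathway	K00626	ACCOA	BUCOA	butyrate
AFT_40	KO-pathway	K01034;K01035	BUCOA	butyrate	butyrate
AFT_41	KO-pathway	K00634	BUCOA	butyrate	butyrate
AFT_42	KO-pathway	K00929	BUCOA	butyrate	butyrate
AFT_43	KO-pathway	K01574	ACAC	acetone	acetone
AFT_44	KO-pathway	K01938;K00288;K01491	CO2	METHF	WL
AFT_45	KO-pathway	K00297	METHF	ACCOA	WL
AFT_46	KO-pathway	K00004;K03366	ACETOIN	butanediol	butanediol
AFT_47	KO-pathway	K00016	PYR	lactate	lactate
AFT_48	KO-pathway	K01847	lactate	PROPCOA	propionate
AFT_49	KO-pathway	K01848;K01849	lactate	PROPCOA	propionate
AFT_50	KO-pathway	K01026	PROPCOA	propionate	propionate
AFT_51	KO-pathway	K00672	CO2	FH4MPT	methanogenesis
AFT_52	KO-pathway	K01499	FH4MPT	MYLH4MPT	methanogenesis
AFT_53	KO-pathway	K00319	MYLH4MPT	MENH4MPT	methanogenesis
AFT_54	KO-pathway	K13942	MYLH4MPT	MENH4MPT	methanogenesis
AFT_55	KO-pathway	K00320	MENH4MPT	ME4MPT	methanogenesis
AFT_56	KO-pathway	K00577;K00578;K00579;K00580;K00581;K00582;K00583;K00584	ME4MPT	MECOM	methanogenesis
AFT_57	KO-pathway	K00399;K00401;K00402	MECOM	methane	methanogenesis
AFT_58	KO-pathway	K01699;K13919;K13920	LACALD	PRPD	propanediol
AFT_59	KO-pathway	K13922	PRPD	propionate	propanediol
AFT_60	KO-pathway	K13788	ACCOA	acetate	acetate_alt
AFT_61	KO-pathway	K15024	METHF	ACCOA	WL
AFT_62	KO-pathway	K00955	sulfate	APS	sulfur
AFT_63	KO-pathway	K00956;K00957	sulfate	APS	sulfur
AFT_64	KO-pathway	K00958	sulfate	APS	sulfur
AFT_65	KO-pathway	K00394;K00395	APS	SO3	sulfur
AFT_66	KO-pathway	K11180;K11181	SO3	H2S	sulfur
AFT_67	KO-pathway	K00380;K00381	H2S	SO3	sulfur
AFT_68	KO-pathway	K00385	SO3	H2S	sulfur
GH2	GH	GH2	mucin	galactose	mucin_cleavage
GH3	GH	GH3	xylan	xylose	xylan_cleavage
GH5	GH	GH5	cellulose	glucose	cellulose_cleavage
GH8	GH	GH8	xylan	xylose	xylan_cleavage
GH9	GH	GH9	cellulose	glucose	cellulose_cleavage
GH10	GH	GH10	xylan	xylose	xylan_cleavage
GH13	GH	GH13	starch	glucose	starch_cleavage
GH16	GH	GH16	hemicellulose	glucose	hemicellulose_cleavage
GH26	GH	GH26	hemicellulose	mannose	hemicellulose_cleavage
GH28	GH	GH28	pectin	galacturonate	pectin_cleavage
GH29	GH	GH29	mucin	fucose	mucin_cleavage
GH30	GH	GH30	xylan	xylose	xylan_cleavage
GH32	GH	GH32	fructan	fructose	fructan_cleavage
GH33	GH	GH33	mucin	sialate	mucin_cleavage
GH35	GH	GH35	pectin	galactose	pectin_cleavage
GH39	GH	GH39	xylan	xylose	xylan_cleavage
GH43	GH	GH43	pectin	arabinose	pectin_cleavage
GH44	GH	GH44	cellulose	glucose	cellulose_cleavage
GH48	GH	GH48	cellulose	glucose	cellulose_cleavage
GH51	GH	GH51	xylan	arabinose	xylan_cleavage
GH74	GH	GH74	hemicellulose	glucose	hemicellulose_cleavage
GH84	GH	GH84	mucin	glucose	mucin_cleavage
GH91	GH	GH91	fructan	fructose	fructan_cleavage
GH94	GH	GH94	cellulose	glucose	cellulose_cleavage
GH95	GH	GH95	mucin	fucose	mucin_cleavage
GH101	GH	GH101	glycoprotein	galactose	glycoprotein_cleavage
GH115	GH	GH115	xylan	galacturonate	xylan_cleavage
GH120	GH	GH120	xylan	xylose	xylan_cleavage
GH127	GH	GH127	pectin	arabinose	pectin_cleavage
GH129	GH	GH129	glycoprotein	galactose	glycoprotein_cleavage
PL1	PL	PL1	pectin	galacturonate	pectin_cleavage
PL9	PL	PL9	pectin	galacturonate	pectin_cleavage
PL11	PL	PL11	pectin	rhamnose	pectin_cleavage
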