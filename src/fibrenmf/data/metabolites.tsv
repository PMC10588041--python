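metabolite_id	compartment
cellulose	extracellular
hemicellulose	extracellular
xylan	extracellular
starch	extracellular
pectin	extracellular
fructan	extracellular
mucin	extracellular
glycoprotein	extracellular
glucose	extracellular
fructose	extracellular
mannose	extracellular
galactose	extracellular
arabinose	extracellular
xylose	extracellular
fucose	extracellular
rhamnose	extracellular
sialate	extracellular
galacturonate	extracellular
gluconate	extracellular
lactate	extracellular
acetate	extracellular
butyrate	extracellular
propionate	extracellular
butanediol	extracellular
acetone	extracellular
methane	extracellular
H2S	extracellular
sulfate	extracellular
CO2	extracellular
G6P	intracellular
F6P	intracellular
FBP	intracellular
GAP	intracellular
PG3	intracellular
PEP	intracellular
PYR	intracellular
PGLCN	intracellular
KDPG	intracellular
KDG	intracellular
GAL1P	intracellular
FUCULOSE	intracellular
FUC1P	intracellular
LACALD	intracellular
PRPD	intracellular
RIB5P	intracellular
XYL5P	intracellular
ACCOA	intracellular
ACAC	intracellular
BUCOA	intracellular
ACETOIN	intracellular
METHF	intracellular
FH4MPT	intracellular
MYLH4MPT	intracellular
MENH4MPT	intracellular
ME4MPT	intracellular
MECOM	intracellular
APS	intracellular
SO3	intracellular
PROPCOA	intracellular
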