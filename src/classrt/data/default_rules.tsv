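# classrt default functional-group taxonomy
# columns: rule_id <TAB> smarts <TAB> weight <TAB> superclass <TAB> subclass
# Higher weight = more specific group; the highest-weight match wins.
acid01	c[CX3](=O)[OX2H1]	8.0	organic acids and derivatives	benzoic acids
acid02	[CX3](=O)[OX2H1]	6.0	organic acids and derivatives	carboxylic acids
acid03	[CX3](=O)[OX2][#6;!$([CX3]=O)]	5.0	organic acids and derivatives	carboxylic acid esters
acid04	[CX3](=O)[NX3]	6.5	organic acids and derivatives	carboxamides
acid05	[CX3](=O)[OX2][CX3](=O)	7.0	organic acids and derivatives	acid anhydrides
nitr01	[NX3;H2;!$(N=*)][CX4]	4.0	organic nitrogen compounds	primary amines
nitr02	[NX3;H1;!$(N=*)]([CX4])[CX4]	3.6	organic nitrogen compounds	secondary amines
nitr03	[NX3;H0;!$(N=*);!$(N-[!#6])]([CX4])([CX4])[CX4]	3.4	organic nitrogen compounds	tertiary amines
nitr04	[NX1]#[CX2]	6.0	organic nitrogen compounds	nitriles
nitr05	[NX3;H2][c]	4.1	organic nitrogen compounds	arylamines
nitr06	[NX3+](=O)[O-]	6.2	organic nitrogen compounds	nitro compounds
nitr07	[NX3][CX3](=[NX2])[NX3]	5.8	organic nitrogen compounds	guanidines
oxyg01	[OX2H][CX4]	2.5	organic oxygen compounds	alcohols
oxyg02	[OD2]([#6])[#6]	2.0	organic oxygen compounds	ethers
oxyg03	[#6][CX3](=O)[#6]	3.0	organic oxygen compounds	ketones
oxyg04	[CX3H1](=O)[#6]	3.5	organic oxygen compounds	aldehydes
sulf01	[SX4](=O)(=O)[NX3]	9.0	organosulfur compounds	sulfonamides
sulf02	[SX4](=O)(=O)([#6])[#6]	6.8	organosulfur compounds	sulfones
sulf03	[SX3](=O)([#6])[#6]	6.4	organosulfur compounds	sulfoxides
sulf04	[SX2H]	5.5	organosulfur compounds	thiols
sulf05	[SX2]([#6])[#6]	4.5	organosulfur compounds	thioethers
halo01	[#6][F,Cl,Br,I]	1.5	organohalogen compounds	halogenated hydrocarbons
hetc01	[nR]	3.2	organoheterocyclic compounds	aromatic nitrogen heterocycles
hetc02	[oR]	3.1	organoheterocyclic compounds	aromatic oxygen heterocycles
hetc03	[sR]	3.15	organoheterocyclic compounds	aromatic sulfur heterocycles
hetc04	[NX3R;!$(N=*)]	2.8	organoheterocyclic compounds	azacycles
hetc05	[OX2R]	2.7	organoheterocyclic compounds	oxacycles
benz01	[OX2H]c	5.0	benzenoids	phenols
benz02	c1ccccc1	1.0	benzenoids	benzene and substituted derivatives
phen01	c[CH]=[CH][CX3]=O	4.2	phenylpropanoids and polyketides	cinnamic acids and derivatives
phen02	o1c(=O)ccc2ccccc12	4.6	phenylpropanoids and polyketides	coumarins and derivatives
alka01	[#7;R2]	4.0	alkaloids and derivatives	polycyclic nitrogen alkaloids
lipi01	[CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2]	2.6	lipids and lipid-like molecules	long-chain aliphatics
lipi02	[CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX3](=O)[OX2H1]	6.1	lipids and lipid-like molecules	fatty acids
lign01	[c][c]([OX2][CH3])[c]([OX2H])	4.4	lignans, neolignans and related compounds	methoxyphenols
dipo01	[NX2]=[NX2+]=[NX1-]	7.2	organic 1,3-dipolar compounds	azides
dipo02	[CX3]=[NX2+]=[NX1-]	7.1	organic 1,3-dipolar compounds	diazo compounds
phos01	[PX4](=O)([OX2])([OX2])	7.6	organophosphorus compounds	phosphate esters
phos02	[#15]	3.8	organophosphorus compounds	other organophosphorus compounds
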