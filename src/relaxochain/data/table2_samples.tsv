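formula	name	mw_gmol	chain_length	status	purity	viscosity_cp
C3H8O3	Glycerol	92	3	Liquid, viscous	98%	1500
C4H8O3	Glyceraldehyde	104	4	Liquid	98%	14.7
C6H14O5	Diglycerol	166	6	Liquid, viscous	80%	5600
C6H12O3	Ketal glycerol	132	6	Liquid	>=95%	N/A
C7H12ClN3O2	Clove oil	205.5	7	Liquid	AR, >=80%	14.2
C10H16	Turpentine	136	10	Liquid	AR	2.1
C10H18O	Terpineol	154	10	Liquid	AR	68
C12H20O6	Glyceryl tripropanoate	260	12	Liquid	>=95%	8.7
C12H20O2	Turpentine acetate	196	12	Liquid	>=97%	N/A
C15H26O6	Tributyrin	302	15	Liquid	98%	9.2
C18H34O2	Oleic acid	282	18	Liquid	AR	17.6
C18H37N	Oleylamine	267	18	Solid	80-90%	7.2
C18H36O	Oleyl alcohol	268	18	Liquid	80-85%	15.32
C19H36O2	Methyl oleate	296	19	Liquid	99%	5.5
C20H36O2	Linoleic acid ethyl ester	308	20	Liquid	>=97%	4.88
C20H38O2	Ethyl oleate	310	20	Liquid	75%	5.15
C21H20O6	Ginger butter	368	21	Liquid	>=98%	N/A
C21H42O4	Propylene glycol oleate	358	21	Liquid	95%	5.1
C22H42O2	Butyl oleate	338	22	Liquid	AR	4.8
C24H38O4	Perilla leaf oil	390	24	Liquid	>=55%	1.7
C24H47NO4	Triethanolamine oleic acid soap	413	24	Liquid	92%	235
C27H50O6	Trioctanoin	470	27	Liquid	>=99%	N/A
C30H62O21	Decaprenylglycerol	758	30	Solid	98%	N/A
C38H46N2O8	Cocamine	658	38	Solid	98%	N/A
C39H76O5	Distearate	624	39	Solid	97%	N/A
C39H74O6	Glycerol trilaurate	638	39	Solid	98%	N/A
C45H76O2	Linoleate cholesteryl ester	648	45	Solid	95%	N/A
C51H98O6	Tripalmitin	806	51	Solid	98%	N/A
C57H110O6	Tristearin	890	57	Solid	98%	N/A
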