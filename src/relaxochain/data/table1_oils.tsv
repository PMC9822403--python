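formula	name	chain_length	status	t2_ms	r2_per_s	r2_over_eta	viscosity_cp
C3H8O3	Glycerol	3	liquid	10	93.95189	0.062635	1500
C4H8O3	Glyceraldehyde	4	liquid	451	2.214346	0.150636	14.7
C6H12O3	Diglycerol	6	liquid	1.3	725.8648	0.129619	5600
C7H12ClN3O2	Ketal glycerol	7	liquid	520	1.921587	0.135323	14.2
C10H18O	Terpineol	10	liquid	50	19.69276	0.252471	78
C12H20O6	Tripropionin	12	liquid	362	2.755334	0.316705	8.7
C15H26O6	Tributyrin	15	liquid	325	3.073538	0.33408	9.2
C18H34O2	Oleic acid	18	liquid	153	6.524779	0.370726	17.6
C18H37N	Oleylamine	18	liquid	404	2.470074	0.343066	7.2
C18H36O	Oleyl alcohol	18	liquid	171	5.838505	0.381103	15.32
C19H36O2	Methyl oleate	19	liquid	520	1.921587	0.34938	5.5
C20H36O2	Ethyl linoleate	20	liquid	503	1.985095	0.406782	4.88
C20H38O2	Ethyl oleate	20	liquid	520	1.920025	0.37282	5.15
C21H20O6	Curcuma oil	21	liquid	480	2.082722	0.408377	5.1
C22H42O2	Butyl oleate	22	liquid	465	2.147456	0.447387	4.8
C24H38O4	Perilla leaf oil	24	liquid	1266	0.789854	0.46462	1.7
C24H47NO4	Triethanolamine oleic acid soap	24	liquid	8.5	117.3367	0.499305	235
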