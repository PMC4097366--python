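screen	category	rank	gene_id	statistic	p_value
wt	SL	1	SPAC24H6.03		
wt	SL	2	SPAC1687.15		
wt	SL	3	SPAC3G9.07c		
wt	SL	4	SPBC6B1.10		
wt	SL	5	SPAPYUG7.04c		
wt	SL	6	SPBC24C6.11		
wt	SL	7	SPBC1734.08		
wt	SL	8	SPAC23D3.09		
wt	SL	9	SPAC17A5.11		
wt	SL	10	SPAC16A10.05c		
wt	SL	11	SPCP1E11.07c		
wt	SL	12	SPBC146.13c		
wt	SL	13	SPAC821.09		
wt	SL	14	SPBC23E6.09		
wt	SL	15	SPCC1682.16		
wt	SL	16	SPBC106.01		
wt	SL	17	SPCC622.16c		
wt	SL	18	SPAC22H10.07		
wt	SL	19	SPBC13G1.13		
wt	SL	20	SPBC16H5.06		
wt	SL	21	SPBC29A10.05		
wt	SL	22	SPBC28F2.07		
wt	SL	23	SPCC1827.08c		
wt	SL	24	SPAC9G1.10c		
wt	SL	25	SPBC83.03c		
wt	SL	26	SPBC342.04		
wt	SL	27	SPCC4G3.19		
wt	SL	28	SPAC9G1.05		
wt	SL	29	SPCC4E9.02		
wt	SL	30	SPCC794.11c		
wt	SL	31	SPBC216.06c		
wt	SL	32	SPCC1450.05c		
wt	SL	33	SPAC22A12.16		
wt	SL	34	SPAC12B10.07		
wt	SL	35	SPAC4A8.05c		
wt	SL	36	SPAC1B9.02c		
wt	SL	37	SPAC16C9.05		
wt	SL	38	SPAC23H3.08c		
wt	SL	39	SPAC2F7.04		
wt	SL	40	SPAC22H12.02		
wt	SL	41	SPBC725.02		
wt	SL	42	SPAC21E11.03c		
wt	SL	43	SPBC12C2.02c		
wt	SL	44	SPBC21B10.13c		
wt	SL	45	SPAC1687.13c		
wt	SL	46	SPBC3F6.05		
wt	SL	47	SPBC4B4.03		
wt	SL	48	SPAC222.16c		
wt	SL	49	SPAC4F10.04		
wt	SL	50	SPAC19B12.10		
wt	SL	51	SPBC2G2.02		
wt	SL	52	SPAC1834.04		
wt	SL	53	SPAPB1E7.12		
wt	SL	54	SPCC320.08		
wt	SL	55	SPCC830.07c		
wt	SL	56	SPAC4G9.05		
wt	SL	57	SPBC13G1.14c		
wt	SS	1	SPBC365.06		
wt	SS	2	SPAC11G7.02		
wt	SS	3	SPCC31H12.05c		
wt	SS	4	SPBC31F10.13c		
wt	SS	5	SPCC1620.14c		
wt	SS	6	SPAC57A10.02		
wt	SS	7	SPAC1556.01c		
wt	SS	8	SPAC30D11.13		
wt	SS	9	SPCC970.07c		
wt	SS	10	SPAC23H4.12		
wt	SS	11	SPCC11E10.08		
wt	SS	12	SPBC21D10.12		
wt	SS	13	SPCC1672.06c		
wt	SS	14	SPAC3C7.03c		
wt	SS	15	SPBC32F12.02		
wt	SS	16	SPCC736.04c		
wt	SS	17	SPBC30D10.13c		
wt	SS	18	SPCC737.09c		
wt	SS	19	SPBC56F2.01		
wt	SS	20	SPBC2F12.11c		
wt	SS	21	SPBC16A3.07c		
wt	SS	22	SPAC5D6.05		
wt	SS	23	SPAC18G6.02c		
wt	SS	24	SPAC19D5.01		
wt	SS	25	SPAC688.11		
wt	SS	26	SPAC227.07c		
wt	SS	27	SPAC1851.04c		
wt	SS	28	SPBC16H5.07c		
wt	SS	29	SPAC17A5.18c		
wt	SS	30	SPBC725.11c		
wt	SS	31	SPAC23C11.08		
wt	SS	32	SPBC3B8.02		
wt	SS	33	SPBC17D1.06		
wt	SS	34	SPAC11E3.06		
wt	SS	35	SPCC663.01c		
wt	SS	36	SPAC167.04		
wt	SS	37	SPAC14C4.12c		
wt	SS	38	SPBC2A9.06c		
wt	SS	39	SPAC24H6.13		
wt	SS	40	SPAPB1A10.03		
wt	SS	41	SPAC12G12.03		
wt	SS	42	SPCC663.03		
wt	SS	43	SPBC1539.10		
wt	SS	44	SPCC1223.05c		
wt	SS	45	SPCC31H12.04c		
wt	SS	46	SPCC1739.08c		
wt	SS	47	SPAC2C4.07c		
wt	SS	48	SPAC1142.08		
mut	SL	1	SPBC8D2.01		
mut	SL	2	SPBC6B1.10		
mut	SL	3	SPBC216.05		
mut	SL	4	SPCC1795.01c		
mut	SL	5	SPBC24C6.11		
mut	SL	6	SPBC1734.08		
mut	SL	7	SPAC9.13c		
mut	SL	8	SPAC23D3.09		
mut	SL	9	SPAC57A10.02		
mut	SL	10	SPAC16A10.05c		
mut	SL	11	SPCC895.07		
mut	SL	12	SPCP31B10.05		
mut	SL	13	SPCC550.12		
mut	SL	14	SPAC23H4.12		
mut	SL	15	SPBC11C11.02		
mut	SL	16	SPBC1289.11		
mut	SL	17	SPCC126.02c		
mut	SL	18	SPBC13G1.13		
mut	SL	19	SPCC188.13c		
mut	SL	20	SPCC663.12		
mut	SL	21	SPCC338.05c		
mut	SL	22	SPAC343.11c		
mut	SL	23	SPCC1919.03c		
mut	SL	24	SPAC343.18		
mut	SL	25	SPCC737.09c		
mut	SL	26	SPBC106.16		
mut	SL	27	SPAC3A11.14c		
mut	SL	28	SPAC589.02c		
mut	SL	29	SPCC1450.05c		
mut	SL	30	SPAC8F11.03		
mut	SL	31	SPAC13A11.04c		
mut	SL	32	SPAC1952.07		
mut	SL	33	SPAC14C4.03		
mut	SL	34	SPAC19G12.06c		
mut	SL	35	SPAC2F7.04		
mut	SL	36	SPAC1006.09		
mut	SL	37	SPAC17G6.04c		
mut	SL	38	SPAC22H12.02		
mut	SL	39	SPBC725.02		
mut	SL	40	SPAC140.01		
mut	SL	41	SPAC1805.04		
mut	SL	42	SPBC1709.10c		
mut	SL	43	SPBC577.15c		
mut	SL	44	SPAC1420.03		
mut	SL	45	SPBC29A10.03c		
mut	SL	46	SPAC4F10.04		
mut	SL	47	SPAPB1E7.12		
mut	SL	48	SPCC320.08		
mut	SL	49	SPCC830.07c		
mut	SL	50	SPAC4G9.05		
mut	SL	51	SPBC13G1.14c		
mut	SL	52	SPCC24B10.08c		
mut	SL	53	SPAC4H3.03c		
mut	SL	54	SPAC1805.05		
mut	SS	1	SPAC11G7.02		
mut	SS	2	SPCC13B11.01		
mut	SS	3	SPBC2G2.03c		
mut	SS	4	SPBC31F10.13c		
mut	SS	5	SPCC1620.14c		
mut	SS	6	SPAC3G6.02		
mut	SS	7	SPAC1556.01c		
mut	SS	8	SPAC821.05		
mut	SS	9	SPBC6B1.04		
mut	SS	10	SPCC1919.15		
mut	SS	11	SPBC23E6.09		
mut	SS	12	SPBC21D10.11c		
mut	SS	13	SPAC22H10.07		
mut	SS	14	SPCC338.08		
mut	SS	15	SPBP35G2.08c		
mut	SS	16	SPBC29A3.14c		
mut	SS	17	SPAC29A4.18		
mut	SS	18	SPBC1921.03c		
mut	SS	19	SPBC2F12.11c		
mut	SS	20	SPAPB1E7.02c		
mut	SS	21	SPAC17A5.16		
mut	SS	22	SPAC20H4.03c		
mut	SS	23	SPCC1259.03		
mut	SS	24	SPAC18G6.02c		
mut	SS	25	SPAPB1E7.06c		
mut	SS	26	SPAC1851.04c		
mut	SS	27	SPAC13G7.06		
mut	SS	28	SPBC725.11c		
mut	SS	29	SPCC1739.12		
mut	SS	30	SPCC663.01c		
mut	SS	31	SPBC21C3.02c		
mut	SS	32	SPAC1F7.09c		
mut	SS	33	SPBC365.11		
mut	SS	34	SPAC144.04c		
mut	SS	35	SPCC4F11.03c		
mut	SS	36	SPAC4G8.03c		
mut	SS	37	SPBP8B7.06		
mut	SS	38	SPCC1223.05c		
mut	SS	39	SPAC1556.05c		
mut	SS	40	SPBC16C6.03c		
mut	SS	41	SPBC2G2.07c		
mut	SS	42	SPAC31G5.12c		
mut	SS	43	SPAC4G9.15		
mut	SS	44	SPAC25B8.05		
mut	SS	45	SPAC1071.07c		
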