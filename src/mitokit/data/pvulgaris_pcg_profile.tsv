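gene	length_bp	start_codon	stop_codon	direction
atp1	1527	ATG	TGA	F
atp4	588	ATG	TAA	F
atp6	726	ATG	TAG	F
atp8	483	ATG	TAA	R
atp9	225	ATG	TAA	R
ccmB	621	ATG	TGA	F
ccmC	741	ATG	TGA	R
ccmFC	1329	ATG	CGA	F
ccmFN	1740	ATG	TGA	R
cob	1176	ATG	TAG	F
cox1	1584	ATG	TAA	F
cox3	798	ATG	TGA	F
matR	2010	ATG	TGA	F
mttB	723	ACG	TGA	F
nad1	978	ACG	TAA	F
nad2	1467	ATG	TAA	R
nad3	357	ATG	TAA	R
nad4	1488	ATG	TGA	R
nad4L	303	ACG	TAA	F
nad5	2019	ATG	TAA	F/R
nad6	618	ATG	TAA	F
nad7	1185	ATG	TAG	R
nad9	573	ATG	TAA	F
rpl5	558	ATG	TAA	F
rpl16	516	ATG	TAA	F
rps1	618	ATG	TAA	R
rps3	1689	ATG	TAG	F
rps4	1041	ATG	TAA	F
rps10	363	ACG	TGA	F
rps12	378	ATG	TGA	R
rps14	303	ATG	TAG	F
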