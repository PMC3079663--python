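gene	nucleic_acid	amino_acid	mutation_type	snp_type
atp1	204T-G		S	transversion
atp4	249G-T	84Glu-Pro	N	transversion
atp4	250G-C	84Glu-Pro	N	transversion
atp4	251A-C	84Glu-Pro	N	transversion
ccmFN	306C-A		S	transversion
ccmFN	906A-C		S	transversion
ccmFN	1103A-T	368Gln-Leu	N	transversion
cox1	1575A-G		S	transition
cox1	1456T-A	486Cys-Ser	N	transversion
cox3	157A-C	53Ile-Leu	N	transversion
cox3	687G-T	229Gln-His	N	transversion
cox3	688A-C	230Met-Leu	N	transversion
matR	1302T-G		S	transversion
nad3	185T-C	62Leu-Pro	N	transition
nad4	804C-A		S	transversion
nad4	822G-A		S	transition
nad4	1290G-T		S	transversion
nad4	1476C-A		S	transversion
rps1	398C-T	133Thr-Ile	N	transition
rps13	45A-C		S	transversion
rps2	837A-T	280Gln-Lys	N	transversion
rps2	838C-A	280Gln-Lys	N	transversion
rps2	845G-C	282Ser-Thr	N	transversion
rps2	961C-A	321His-Asn	N	transversion
rps2	1002G-T		S	transversion
rps2	1062C-A		S	transversion
rps3	256C-A	86Gln-Lys	N	transversion
rps3	505G-T	169Asp-Phe	N	transversion
rps3	505A-T	169Asp-Phe	N	transversion
rps3	1333A-C	445Lys-Gln	N	transversion
rps4	146G-T	49Arg-Leu	N	transversion
rps4	236T-G	79Leu-Arg	N	transversion
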