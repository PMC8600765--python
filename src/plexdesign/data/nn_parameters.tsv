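# Nearest-neighbour DNA duplex thermodynamic parameters (1 M NaCl reference state).
# Watson-Crick stacks and initiation terms: unified oligonucleotide parameters
# (SantaLucia & Hicks 2004). Single internal mismatch stacks: Allawi & SantaLucia
# 1997-1998 (G.T, A.C, G.A, C.T) and Peyret et al. 1999 (A.A, C.C, G.G, T.T).
# Columns: kind<TAB>key<TAB>dH_kcal_per_mol<TAB>dS_cal_per_mol_K
# Key convention: "XY/WZ" = top strand 5'-XY-3' paired with bottom strand 3'-WZ-5'.
# version: 1
init	init	0.2	-5.7
init	init_5T/A	0.0	0.0
init	init_A/T	2.2	6.9
init	init_G/C	0.0	0.0
init	init_allA/T	0.0	0.0
init	init_oneG/C	0.0	0.0
init	sym	0.0	-1.4
stack	AA/TT	-7.6	-21.3
stack	AT/TA	-7.2	-20.4
stack	CA/GT	-8.5	-22.7
stack	CG/GC	-10.6	-27.2
stack	CT/GA	-7.8	-21.0
stack	GA/CT	-8.2	-22.2
stack	GC/CG	-9.8	-24.4
stack	GG/CC	-8.0	-19.9
stack	GT/CA	-8.4	-22.4
stack	TA/AT	-7.2	-21.3
mismatch	AA/TA	1.2	1.7
mismatch	AA/TC	2.3	4.6
mismatch	AA/TG	-0.6	-2.3
mismatch	AC/TA	5.3	14.6
mismatch	AC/TC	0.0	-4.4
mismatch	AC/TT	0.7	0.2
mismatch	AG/TA	-0.7	-2.3
mismatch	AG/TG	-3.1	-9.5
mismatch	AG/TT	1.0	0.9
mismatch	AT/TC	-1.2	-6.2
mismatch	AT/TG	-2.5	-8.3
mismatch	AT/TT	-2.7	-10.8
mismatch	CA/GA	-0.9	-4.2
mismatch	CA/GC	1.9	3.7
mismatch	CA/GG	-0.7	-2.3
mismatch	CC/GA	0.6	-0.6
mismatch	CC/GC	-1.5	-7.2
mismatch	CC/GT	-0.8	-4.5
mismatch	CG/GA	-4.0	-13.2
mismatch	CG/GG	-4.9	-15.3
mismatch	CG/GT	-4.1	-11.7
mismatch	CT/GC	-1.5	-6.1
mismatch	CT/GG	-2.8	-8.0
mismatch	CT/GT	-5.0	-15.8
mismatch	GA/CA	-2.9	-9.8
mismatch	GA/CC	5.2	14.2
mismatch	GA/CG	-0.6	-1.0
mismatch	GC/CA	-0.7	-3.8
mismatch	GC/CC	3.6	8.9
mismatch	GC/CT	2.3	5.4
mismatch	GG/CA	0.5	3.2
mismatch	GG/CG	-6.0	-15.8
mismatch	GG/CT	3.3	10.4
mismatch	GG/TT	5.8	16.3
mismatch	GT/CC	5.2	13.5
mismatch	GT/CG	-4.4	-12.3
mismatch	GT/CT	-2.2	-8.4
mismatch	GT/TG	4.1	9.5
mismatch	TA/AA	4.7	12.9
mismatch	TA/AC	3.4	8.0
mismatch	TA/AG	0.7	0.7
mismatch	TC/AA	7.6	20.2
mismatch	TC/AC	6.1	16.4
mismatch	TC/AT	1.2	0.7
mismatch	TG/AA	3.0	7.4
mismatch	TG/AG	1.6	3.6
mismatch	TG/AT	-0.1	-1.7
mismatch	TG/GT	-1.4	-6.2
mismatch	TT/AC	1.0	0.7
mismatch	TT/AG	-1.3	-5.3
mismatch	TT/AT	0.2	-1.5
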