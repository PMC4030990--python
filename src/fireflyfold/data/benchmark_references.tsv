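# Reference minimum energies for the packaged benchmark sequences.
# columns: id, lattice, model, reference energy, label
id	lattice	model	energy	label
HP1	cubic	hp	-32	E_bench
HP1	fcc	hp	-69	E_nat
HP2	cubic	hp	-34	E_bench
HP2	fcc	hp	-69	E_nat
HP3	cubic	hp	-34	E_bench
HP3	fcc	hp	-72	E_nat
HP4	cubic	hp	-33	E_bench
HP4	fcc	hp	-71	E_nat
HP5	cubic	hp	-32	E_bench
HP5	fcc	hp	-70	E_nat
HP6	cubic	hp	-32	E_bench
HP6	fcc	hp	-70	E_nat
HP7	cubic	hp	-32	E_bench
HP7	fcc	hp	-70	E_nat
HP8	cubic	hp	-31	E_bench
HP8	fcc	hp	-69	E_nat
HP9	cubic	hp	-34	E_bench
HP9	fcc	hp	-71	E_nat
HP10	cubic	hp	-33	E_bench
HP10	fcc	hp	-68	E_nat
MJ1	cubic	mjb	-25.85	E_nat
MJ2	cubic	mjb	-25.92	E_nat
MJ3	cubic	mjb	-26.09	E_nat
MJ4	cubic	mjb	-25.87	E_nat
MJ5	cubic	mjb	-26.15	E_nat
MJ6	cubic	mjb	-26.24	E_nat
4RXN	fcc	berrera	-166.88	E_pub
1ENH	fcc	berrera	-153.79	E_pub
4PTI	fcc	berrera	-210.29	E_pub
2IGD	fcc	berrera	-183.18	E_pub
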