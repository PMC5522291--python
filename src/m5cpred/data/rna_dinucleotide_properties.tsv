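property	AA	AC	AG	AU	CA	CC	CG	CU	GA	GC	GG	GU	UA	UC	UG	UU
shift	-0.08	0.23	-0.04	-0.06	0.11	-0.01	0.30	-0.04	0.07	0.07	-0.01	0.23	-0.02	0.07	0.11	-0.08
slide	-1.27	-1.43	-1.50	-1.36	-1.46	-1.78	-1.89	-1.50	-1.70	-1.39	-1.78	-1.43	-1.45	-1.70	-1.46	-1.27
rise	3.18	3.24	3.30	3.24	3.09	3.32	3.30	3.30	3.38	3.22	3.32	3.24	3.26	3.38	3.09	3.18
tilt	-0.80	0.80	0.50	1.10	1.00	0.30	-0.10	0.50	1.30	0.00	0.30	0.80	-0.20	1.30	1.00	-0.80
roll	7.00	4.80	8.50	7.10	9.90	8.70	12.10	8.50	9.40	6.10	8.70	4.80	10.70	9.40	9.90	7.00
twist	31.00	32.00	30.00	33.00	31.00	32.00	27.00	30.00	32.00	35.00	32.00	32.00	32.00	32.00	31.00	31.00
stacking_energy	-13.70	-13.80	-14.00	-15.40	-14.40	-11.10	-15.60	-14.00	-14.20	-16.90	-11.10	-13.80	-16.00	-14.20	-14.40	-13.70
enthalpy	-6.60	-10.20	-7.60	-5.70	-10.50	-12.20	-8.00	-7.60	-13.30	-14.20	-12.20	-10.20	-8.10	-13.30	-10.50	-6.60
entropy	-18.40	-26.20	-19.20	-15.50	-27.80	-29.70	-19.40	-19.20	-35.50	-34.90	-29.70	-26.20	-22.60	-35.50	-27.80	-18.40
free_energy	-0.90	-2.10	-1.70	-0.90	-1.80	-2.90	-2.00	-1.70	-2.30	-3.40	-2.90	-2.10	-1.10	-2.30	-1.80	-0.90
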