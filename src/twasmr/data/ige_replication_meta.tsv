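gene	discovery_q	discovery_p	meta_p
IL5RA	3.37E-36	1.88E-40	8.08E-12
CLC	2.15E-28	3.60E-32	5.00E-24
EMR1	4.04E-25	1.13E-28	1.89E-11
ADORA3	2.15E-18	1.32E-21	2.02E-08
SMPD3	7.55E-17	5.92E-20	2.14E-16
PRSS33	5.92E-15	5.30E-18	2.51E-27
CAT	4.82E-14	4.86E-17	4.50E-07
SIGLEC8	1.43E-12	1.52E-15	1.07E-21
IDO1	2.86E-12	3.20E-15	5.50E-19
VSTM1	4.24E-11	5.22E-14	1.32E-15
CD200R1	3.76E-10	4.84E-13	1.23E-05
ARHGAP10	5.94E-10	7.98E-13	9.93E-06
CCR3	1.67E-09	2.38E-12	7.13E-15
CEBPE	1.67E-09	2.43E-12	1.99E-28
GPR114	3.73E-09	5.64E-12	1.61E-08
ANXA1	4.59E-09	7.19E-12	3.81E-05
CAMK1	8.95E-09	1.50E-11	5.10E-14
RNASE2	1.16E-08	2.02E-11	4.47E-09
LGALS12	2.54E-08	4.70E-11	8.22E-15
OLIG2	7.58E-08	1.53E-10	4.34E-29
C6orf97	1.19E-07	2.53E-10	8.94E-05
CD9	1.91E-07	4.27E-10	1.19E-06
P2RY14	2.26E-07	5.18E-10	2.06E-04
EEF2K	2.66E-07	6.26E-10	2.57E-11
SRGAP3	5.07E-07	1.25E-09	2.24E-09
INPP1	5.08E-07	1.28E-09	3.49E-14
CCL23	8.26E-07	2.13E-09	9.65E-25
TRERF1	1.23E-06	3.22E-09	5.43E-08
CD24	5.68E-06	1.65E-08	1.20E-04
FBP1	7.01E-06	2.08E-08	7.75E-08
PNPLA6	1.46E-05	4.81E-08	6.57E-07
SLC4A8	1.46E-05	4.91E-08	1.53E-04
GAPT	1.51E-05	5.16E-08	6.99E-06
SLC16A14	2.74E-05	1.03E-07	7.63E-08
ARHGEF6	3.80E-05	1.45E-07	1.15E-04
SIGLEC10	4.01E-05	1.55E-07	6.95E-08
DSC2	7.50E-05	3.02E-07	1.16E-06
BACE2	2.15E-04	9.61E-07	2.96E-09
GPR44	2.66E-04	1.21E-06	1.29E-21
THBS4	3.39E-04	1.59E-06	1.93E-11
OLIG1	5.89E-04	3.03E-06	1.88E-20
VLDLR	1.20E-03	6.71E-06	5.59E-05
PLIN2	1.39E-03	8.11E-06	1.42E-05
ACACB	1.57E-03	9.30E-06	1.41E-08
FAM124B	2.41E-03	1.56E-05	3.22E-09
CYP4F12	2.47E-03	1.61E-05	3.26E-13
PAPSS1	4.95E-03	3.41E-05	9.11E-06
SLC24A3	6.67E-03	4.74E-05	1.34E-05
IL17RB	1.18E-02	9.20E-05	1.60E-06
GFI1B	1.55E-02	1.23E-04	6.42E-07
TRIB1	1.64E-02	1.35E-04	2.53E-05
CD63	1.64E-02	1.36E-04	1.66E-04
SUSD1	1.72E-02	1.45E-04	6.13E-05
FCRLA	1.91E-02	1.71E-04	8.03E-05
BRI3BP	2.04E-02	1.94E-04	6.87E-06
GPR137B	2.23E-02	2.15E-04	3.10E-05
CACNG6	2.46E-02	2.43E-04	7.74E-05
SPNS3	3.76E-02	4.12E-04	2.76E-18
C3AR1	4.18E-02	4.81E-04	1.04E-06
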