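# Standard atomic isotope masses (Da) and abundances (mole fraction), NIST/CIAAW values.
# Columns: element symbol, extra-neutron index k (relative to the lightest stable isotope),
# isotopic mass, isotopic abundance. Radioactive "gap" isotopes (e.g. 35S) are listed with
# abundance 0 so that each element's coefficient vector is dense in k.
# version: nist-2018
H	0	1.00782503207	0.999885
H	1	2.01410177812	0.000115
C	0	12.0	0.9893
C	1	13.00335483507	0.0107
N	0	14.00307400443	0.99636
N	1	15.00010889888	0.00364
O	0	15.99491461957	0.99757
O	1	16.99913175650	0.00038
O	2	17.99915961286	0.00205
S	0	31.9720711744	0.9499
S	1	32.9714589098	0.0075
S	2	33.967867004	0.0425
S	3	34.969032310	0.0
S	4	35.96708071	0.0001
P	0	30.97376199842	1.0
Cl	0	34.968852682	0.7576
Cl	1	35.968306822	0.0
Cl	2	36.965902602	0.2424
Br	0	78.9183376	0.5069
Br	1	79.9185298	0.0
Br	2	80.9162897	0.4931
Pt	0	189.9599297	0.00012
Pt	1	190.9616729	0.0
Pt	2	191.9610387	0.00782
Pt	3	192.9629824	0.0
Pt	4	193.9626809	0.3286
Pt	5	194.9647917	0.3378
Pt	6	195.96495209	0.2521
Pt	7	196.96734069	0.0
Pt	8	197.9678949	0.07356
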