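# Benchmark set of lac operator mutants: published predicted vs measured
# LacI binding energies (kBT), relative to the O1 reference
# AATTGTGAGCGGATAACAATT, with the number of point mutations per class.
sequence	n_mut_class	predicted_kbt	measured_kbt
AATTGTGAGCGGAGAACAATT	1	-12.63	-12.24
AATTGTGAGCGCATAACAATT	1	-15.71	-15.30
AATTGTGAGCGGATCACAATT	1	-15.22	-14.99
AATTGTGAGCGGAAAACAATT	1	-12.91	-12.50
AATTGCGAGCGGATAACAATT	1	-12.14	-11.30
AATTGTGAGGGGATAACAATT	1	-13.16	-12.35
AATTGTGAGCGGATATCAATT	1	-13.66	-13.29
AATTGTGAGCAGATAACAATT	1	-11.11	-10.25
AATTGTGAGAGGATAACAATT	1	-8.89	-10.00
AATTGTGAGCGGGTAACAACT	2	-13.82	-14.79
AAATGTGAGCGGATAACAACT	2	-13.61	-14.40
AATTGTGAGCGAGTAACAATT	2	-14.36	-15.12
ATTTGTGAGCGGAGAACAATT	2	-12.55	-11.52
CATTGTGAGCGCATAACAATT	2	-15.34	-14.80
AATTGTGAGCGGAACACAATT	2	-12.83	-13.31
AATTGTGAGCGGAATACAATT	2	-11.70	-12.03
AATTGCGAGCGGATAACAAAT	2	-12.06	-10.78
AATTGTGAGGGGATAACAATC	2	-14.13	-12.15
AAATGTGAGCGAGTAACAATT	3	-13.84	-14.57
AATTGTGAGCGAGTAACAACT	3	-13.19	-14.67
ATTTGTGAGCGAAGAACAATT	3	-11.92	-10.83
CATTGTGAGCGCATAACATTT	3	-15.39	-14.18
AATTGTGAGCGGAACACAATG	3	-13.72	-12.17
AATTGTGAGCGGGATACAATT	3	-11.39	-11.86
AATTGCGAGCGGATAACAAAG	3	-12.96	-10.62
AATTGTGAGGGTATAACAATC	3	-14.10	-11.79
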