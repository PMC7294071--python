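tract	hemisphere	r2_ss6000	r2_ss4000	r2_ss2400	r2_ss1200
AF	L	0.50	0.49	0.39	0.35
AF	R	0.46	0.43	0.37	0.33
ATR	L	0.53	0.50	0.43	0.42
ATR	R	0.48	0.42	0.38	0.36
CA	-	0.06	0.03	0.03	0.11
CC	Full	0.44	0.39	0.32	0.31
CC	1	0.05	0.02	0.02	0.05
CC	2	0.45	0.43	0.38	0.38
CC	3	0.48	0.46	0.43	0.42
CC	4	0.35	0.31	0.24	0.25
CC	5	0.22	0.16	0.11	0.06
CC	6	0.34	0.29	0.21	0.14
CC	7	0.31	0.29	0.22	0.18
CG	L	0.38	0.27	0.18	0.10
CG	R	0.21	0.20	0.11	0.06
CST	L	0.34	0.27	0.19	0.16
CST	R	0.29	0.28	0.20	0.15
FX	L	0.06	0.03	0.01	0.01
FX	R	0.05	0.02	0.01	0.01
ICP	L	0.21	0.18	0.11	0.04
ICP	R	0.11	0.11	0.07	0.08
IFOF	L	0.44	0.40	0.34	0.29
IFOF	R	0.46	0.42	0.40	0.33
ILF	L	0.39	0.34	0.27	0.22
ILF	R	0.35	0.26	0.24	0.21
MCP	-	0.07	0.06	0.05	0.08
MLF	L	0.43	0.39	0.30	0.26
MLF	R	0.39	0.34	0.28	0.20
OR	L	0.36	0.30	0.25	0.18
OR	R	0.28	0.25	0.19	0.13
SLF_III	L	0.47	0.44	0.33	0.30
SLF_III	R	0.41	0.38	0.31	0.28
SLF_II	L	0.41	0.40	0.32	0.29
SLF_II	R	0.31	0.29	0.21	0.17
SLF_I	L	0.29	0.24	0.19	0.15
SLF_I	R	0.22	0.20	0.15	0.08
UF	L	0.27	0.23	0.11	0.10
UF	R	0.17	0.09	0.04	0.04
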