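word	Twist	Tilt	Roll	Shift	Slide	Rise
AA	35.1	-1.4	0.7	-0.03	-0.08	3.27
AC	31.5	-0.1	0.7	0.13	-0.58	3.36
AG	31.9	-1.7	4.5	0.09	-0.25	3.34
AT	29.3	0	1.1	0	-0.59	3.31
CA	37.3	0.5	4.7	0.09	0.53	3.33
CC	32.9	-0.1	3.6	0.05	-0.22	3.42
CG	36.1	0	5.4	0	0.41	3.39
CT	31.9	1.7	4.5	-0.09	-0.25	3.34
GA	36.3	-1.5	1.9	-0.28	0.09	3.37
GC	33.6	0	0.3	0	-0.38	3.4
GG	32.9	0.1	3.6	-0.05	-0.22	3.42
GT	31.5	0.1	0.7	-0.13	-0.58	3.36
TA	37.8	0	3.3	0	0.05	3.42
TC	36.3	1.5	1.9	0.28	0.09	3.37
TG	37.3	-0.5	4.7	-0.09	0.53	3.33
TT	35.1	1.4	0.7	0.03	-0.08	3.27
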