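type	strategy	c	m	r	l	gamma
Q	resprouter	0.047	0.0025	0.9	0.0025	0
P	seeder	0.053	0.008	0	0.05	0.04
R	seeder	0.045	0.02	0	0.06666666666666667	0.0016
U	seeder	0.067	0.04	0	0.1	0.0029
C	seeder	0.11	0.06666666666666667	0	0.1	0.00078
B	resprouter	0.22	0.025	0.4	0.1	0
# C_conv	0.014
# epsilon	0.0001
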