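	x1	x2	x3	x4	x5	x6
x1	8.8374	0.479	-0.043	-0.033	0.356	-0.236
x2	0.483	0.1919	0.068	-0.084	-0.224	-0.110
x3	0.220	0.057	8924231.9	0.085	0.552	-0.330
x4	-0.040	-0.133	0.149	20392.4	0.091	0.013
x5	0.253	-0.124	0.523	0.179	1952795.2	0.384
x6	-0.276	-0.314	-0.183	0.064	0.213	1.378
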