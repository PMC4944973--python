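# LCPO coefficients keyed by element and bonded-heavy-neighbour count.
# Calibrated by weighted least squares against Monte-Carlo reference areas
# on randomized bonded clusters (C/N/O/P/S, bond lengths 1.35-1.6 A, probe
# 1.4 A) pooled with atoms harvested from generated toy dimers, covering
# sparse and interface-packed contexts.  Count 0 is the exact isolated
# sphere.  Known bias: near-isolated bonded pairs are overestimated by
# about 7%.
C	0	1.0	0.0	0.0	0.0
C	1	0.797599	-0.345209	0.005418	0.000475
C	2	0.601584	-0.291021	-0.001121	0.000476
C	3	0.386687	-0.163581	0.013750	0.000029
C	4	0.0	0.0	0.0	0.0
N	0	1.0	0.0	0.0	0.0
N	1	0.797599	-0.345209	0.005418	0.000475
N	2	0.601584	-0.291021	-0.001121	0.000476
N	3	0.386687	-0.163581	0.013750	0.000029
O	0	1.0	0.0	0.0	0.0
O	1	0.797599	-0.345209	0.005418	0.000475
O	2	0.601584	-0.291021	-0.001121	0.000476
P	0	1.0	0.0	0.0	0.0
P	1	0.797599	-0.345209	0.005418	0.000475
P	2	0.601584	-0.291021	-0.001121	0.000476
P	3	0.386687	-0.163581	0.013750	0.000029
P	4	0.448584	-0.287560	0.036475	0.000130
S	0	1.0	0.0	0.0	0.0
S	1	0.797599	-0.345209	0.005418	0.000475
S	2	0.601584	-0.291021	-0.001121	0.000476
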