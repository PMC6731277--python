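pam	weight
AA	0.0
AC	0.0
AG	0.26
AT	0.0
CA	0.0
CC	0.0
CG	0.03
CT	0.0
GA	0.07
GC	0.02
GG	1.0
GT	0.02
TA	0.0
TC	0.0
TG	0.03
TT	0.0
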