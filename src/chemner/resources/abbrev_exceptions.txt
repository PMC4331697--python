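# Sentence-splitter exceptions: a period ending one of these strings does
# not terminate a sentence even when followed by whitespace + capital/digit.
# One entry per line, case-sensitive, must end with ".".
e.g.
i.e.
et al.
cf.
ca.
vs.
approx.
Fig.
Figs.
Eq.
Eqs.
Ref.
Refs.
Tab.
No.
Dr.
Prof.
St.
Mr.
Mrs.
Ms.
Jr.
Sr.
Inc.
Ltd.
Co.
Corp.
spp.
sp.
var.
resp.
min.
max.
wt.
vol.
conc.
mol.
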