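# Ion conductance dictionary — derived from the ion current dictionary by
# rewriting "current" -> "conductance" and leading "I" -> "g" in acronyms.
T-type calcium conductance
T-type calcium conductances
T-type Ca2+ conductance
T-type Ca2+ conductances
L-type calcium conductance
L-type calcium conductances
sodium conductance
sodium conductances
potassium conductance
potassium conductances
calcium conductance
calcium conductances
chloride conductance
leak conductance
persistent sodium conductance
transient sodium conductance
hyperpolarization-activated conductance
hyperpolarization-activated cation conductance
A-type potassium conductance
delayed rectifier potassium conductance
inward rectifier potassium conductance
low-threshold calcium conductance
high-threshold calcium conductance
gh
gT
gA
gK
gNa
gCa
gKir
gKC
gNaP
g(Ts)
g(h)
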