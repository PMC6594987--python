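# Ion current dictionary — curated snapshot, one surface form per line.
T-type calcium current
T-type calcium currents
T-type Ca2+ current
T-type Ca2+ currents
L-type calcium current
L-type calcium currents
sodium current
sodium currents
potassium current
potassium currents
calcium current
calcium currents
chloride current
leak current
persistent sodium current
transient sodium current
hyperpolarization-activated current
hyperpolarization-activated cation current
A-type potassium current
delayed rectifier potassium current
inward rectifier potassium current
low-threshold calcium current
high-threshold calcium current
Ih
IT
IA
IK
INa
ICa
IKir
IKC
INaP
I(Ts)
I(h)
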