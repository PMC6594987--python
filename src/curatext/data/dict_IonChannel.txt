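# Ion channel dictionary — curated snapshot, one surface form per line.
T-type calcium channel
T-type calcium channels
T-type Ca2+ channel
T-type Ca2+ channels
L-type calcium channel
L-type calcium channels
sodium channel
sodium channels
potassium channel
potassium channels
calcium channel
calcium channels
chloride channel
chloride channels
HCN channel
HCN channels
HCN1
HCN2
Cav3.1
CaV3.1
Cav3.2
Cav3.3
CaVT
Nav1.1
Nav1.2
Nav1.6
Kv1.1
Kv1.2
Kv3.1
Kir2.1
alpha1G
alpha1H
alpha1I
CACNA1G
CACNA1H
CACNA1I
SCN1A
KCNQ2
GABA(A) receptor channel
NMDA receptor channel
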