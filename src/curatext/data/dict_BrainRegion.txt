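# Brain region dictionary — curated snapshot, one surface form per line.
ventral posterior medial nucleus
ventral posteromedial nucleus
VPM
ventrobasal complex
ventrobasal thalamus
suprachiasmatic nucleus
SCN
thalamus
nucleus
cortex
neocortex
hippocampus
cerebellum
striatum
amygdala
hypothalamus
brainstem
lateral geniculate nucleus
dorsal lateral geniculate nucleus
LGN
thalamic reticular nucleus
nucleus reticularis
TRN
somatosensory cortex
barrel cortex
visual cortex
auditory cortex
motor cortex
prefrontal cortex
entorhinal cortex
dentate gyrus
CA1
CA3
substantia nigra
superior colliculus
inferior colliculus
olfactory bulb
spinal cord
medulla
pons
midbrain
forebrain
basal ganglia
globus pallidus
subthalamic nucleus
red nucleus
locus coeruleus
raphe nucleus
layer 4
layer 5
cortical layer 1
anterodorsal nucleus
centrolateral nucleus
medial geniculate body
zona incerta
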