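# Neuron type dictionary — curated snapshot, one surface form per line.
pyramidal neurons
pyramidal cells
pyramidal neuron
pyramidal cell
Martinotti cells
Martinotti cell
Purkinje cells
Purkinje cell
granule cells
granule cell
basket cells
basket cell
chandelier cells
chandelier cell
stellate cells
stellate cell
relay neurons
relay neuron
relay cells
relay cell
thalamocortical neurons
thalamocortical neuron
thalamo-cortical relay cell
thalamocortical relay cells
TC cells
TC neurons
interneurons
interneuron
GABAergic interneurons
fast-spiking interneurons
mitral cells
motoneurons
motor neurons
dopaminergic neurons
cholinergic neurons
serotonergic neurons
bipolar cells
ganglion cells
retinal ganglion cells
amacrine cells
horizontal cells
place cells
grid cells
medium spiny neurons
corticothalamic neurons
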