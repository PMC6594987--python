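# Model organism dictionary — curated snapshot, one surface form per line.
rat
rats
mouse
mice
rodent
rodents
rabbit
rabbits
cat
cats
ferret
ferrets
monkey
monkeys
macaque
macaques
human
humans
guinea pig
guinea pigs
zebrafish
Xenopus
Drosophila
C. elegans
Rattus norvegicus
Mus musculus
Oryctolagus cuniculus
Macaca mulatta
Wistar rat
Wistar rats
Sprague-Dawley rat
Sprague-Dawley rats
Long-Evans rat
C57BL/6 mice
wild-type
wild type
Genetic Absence Epilepsy Rat from Strasbourg
GAERS
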