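# base unit long name<TAB>short form (24 bases, SI + derived)
volt	V
gram	g
metre	m
second	s
ampere	A
kelvin	K
mole	mol
candela	cd
hertz	Hz
newton	N
pascal	Pa
joule	J
watt	W
coulomb	C
farad	F
ohm	Ω
siemens	S
weber	Wb
tesla	T
henry	H
litre	l
molar	M
gray	Gy
becquerel	Bq
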