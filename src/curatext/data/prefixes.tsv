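# prefix long name<TAB>short form (19 SI prefixes)
yotta	Y
zetta	Z
exa	E
peta	P
tera	T
giga	G
mega	M
kilo	k
hecto	h
deci	d
centi	c
milli	m
micro	µ
nano	n
pico	p
femto	f
atto	a
zepto	z
yocto	y
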