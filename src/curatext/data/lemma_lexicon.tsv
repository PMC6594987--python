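# word<TAB>lemma (lookup is lowercased; identity fallback elsewhere)
were	be
was	be
is	be
are	be
been	be
being	be
am	be
made	make
making	make
makes	make
has	have
had	have
having	have
does	do
did	do
done	do
shown	show
showed	show
seen	see
saw	see
found	find
taken	take
took	take
given	give
gave	give
went	go
gone	go
mice	mouse
children	child
data	datum
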