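# word<TAB>Penn Treebank tag (lookup is lowercased)
the	DT
a	DT
an	DT
this	DT
that	DT
these	DT
those	DT
each	DT
all	DT
some	DT
any	DT
no	DT
both	DT
whole	JJ
posterior	JJ
anterior	JJ
superior	JJ
inferior	JJ
persistent	JJ
spontaneous	JJ
adult	JJ
normal	JJ
orbital	JJ
other	JJ
same	JJ
several	JJ
main	JJ
large	JJ
small	JJ
high	JJ
low	JJ
of	IN
in	IN
on	IN
at	IN
from	IN
with	IN
for	IN
by	IN
during	IN
between	IN
into	IN
through	IN
under	IN
within	IN
around	IN
via	IN
per	IN
as	IN
than	IN
while	IN
after	IN
before	IN
about	IN
due	JJ
to	TO
and	CC
or	CC
but	CC
nor	CC
is	VBZ
are	VBP
was	VBD
were	VBD
be	VB
been	VBN
being	VBG
am	VBP
has	VBZ
have	VBP
had	VBD
do	VBP
does	VBZ
did	VBD
made	VBN
make	VB
makes	VBZ
shown	VBN
seen	VBN
found	VBN
given	VBN
taken	VBN
observed	VBN
can	MD
could	MD
may	MD
might	MD
will	MD
would	MD
shall	MD
should	MD
must	MD
not	RB
also	RB
only	RB
very	RB
mainly	RB
partially	RB
respectively	RB
however	RB
we	PRP
it	PRP
they	PRP
its	PRP$
their	PRP$
our	PRP$
which	WDT
when	WRB
where	WRB
firing	NN
effect	NN
rate	NN
night	NN
mixture	NN
curve	NN
pole	NN
cell	NN
cells	NNS
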