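a
an
and
are
as
at
be
but
by
can
cell
do
for
from
has
have
ice
if
in
is
it
may
not
of
on
or
she
so
that
the
this
to
was
we
were
with
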