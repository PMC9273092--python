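the
is
a
an
and
or
of
at
be
been
being
was
were
are
am
this
that
these
those
it
its
as
if
such
then
than
so
there
here
into
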