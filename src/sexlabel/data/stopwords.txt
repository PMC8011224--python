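cell
cells
line
lines
human
mouse
sample
samples
tissue
culture
cultured
type
strain
with
from
this
that
were
between
other
normal
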