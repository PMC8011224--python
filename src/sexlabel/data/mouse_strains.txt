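c57bl/6
c57bl/6j
balb/c
129s1
dba/2
fvb/n
cd-1
nod/scid
c3h/hej
a/j
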