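none
control
untreated
dmso
na
placebo
saline
pbs
mock
baseline
unstimulated
etoh
ethanol
ctrl
non-treated
vehicle
ctl
no treatment
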