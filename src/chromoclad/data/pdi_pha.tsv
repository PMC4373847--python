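# Painting of PHA-14 and PHA-15 whole-chromosome probes on Phyllostomus
# discolor (PDI): both probes paint whole PDI chromosomes despite the
# metacentric form of PDI-15 (pericentric inversion, painting-invisible).
probe	target	n_blocks	region
PHA-14	PDI-14	1
PHA-15	PDI-15	1
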