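# Painting of Phyllostomus hastatus (PHA) whole-chromosome probes on
# Tonatia saurophila (TSA): 32 homologous segments.
# PHA-1 gave three signals on two chromosomes (TSA-4 and TSA-7); the text does
# not say which chromosome carries two blocks, so the extra block is assigned
# to TSA-4 here. Segment totals do not depend on that choice.
probe	target	n_blocks	region
PHA-1	TSA-4	2
PHA-1	TSA-7	1
PHA-2	TSA-1	1
PHA-2	TSA-2	1
PHA-3	TSA-1	1
PHA-3	TSA-4	1
PHA-4	TSA-1	1
PHA-4	TSA-4	1
PHA-5	TSA-6	2
PHA-6	TSA-1	1
PHA-6	TSA-2	1
PHA-6	TSA-3	1
PHA-6	TSA-5	1
PHA-7	TSA-1	1
PHA-7	TSA-3	1
PHA-8	TSA-3	1
PHA-8	TSA-5	1
PHA-9	TSA-1	1
PHA-9	TSA-5	1
PHA-10	TSA-2	1
PHA-10	TSA-7	1
PHA-11	TSA-5	1
PHA-12	TSA-1	1
PHA-12	TSA-2	1
PHA-13	TSA-1	1
PHA-13	TSA-5	1
PHA-13	TSA-7	1
PHA-14	TSA-6	1
PHA-15	TSA-5	1
PHA-X	TSA-X	1
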