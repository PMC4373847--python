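# Painting of Phyllostomus hastatus (PHA) whole-chromosome probes on
# Lophostoma silvicola (LSI): 17 homologous segments.
# Only PHA-13 is explicitly localized (whole LSI-13 plus the short arm of
# LSI-15); every other probe paints one whole LSI chromosome. The one-to-one
# target assignments other than PHA-13 are inferred from the karyotype
# comparison (LSI differs from PHA only by pairs 13, 15 and 16) and do not
# affect segment counts or the synteny partition shape.
probe	target	n_blocks	region
PHA-1	LSI-1	1
PHA-2	LSI-2	1
PHA-3	LSI-3	1
PHA-4	LSI-4	1
PHA-5	LSI-5	1
PHA-6	LSI-6	1
PHA-7	LSI-7	1
PHA-8	LSI-8	1
PHA-9	LSI-9	1
PHA-10	LSI-10	1
PHA-11	LSI-11	1
PHA-12	LSI-12	1
PHA-13	LSI-13	1
PHA-13	LSI-15	1	p
PHA-14	LSI-14	1
PHA-15	LSI-16	1
PHA-X	LSI-X	1
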