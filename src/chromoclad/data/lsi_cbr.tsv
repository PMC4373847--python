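# note: enumerated signals sum to 25 segments while the source text states a
# note: total of 26; the unaccounted segment is not identifiable from the text.
# Painting of Carollia brevicauda (CBR) whole-chromosome probes on
# Lophostoma silvicola (LSI).
# CBR-2 gave five signals on LSI-2, 4, 8 and 9 and CBR-Y2 three signals on
# LSI-2 and 6; the chromosome carrying the extra block is not named, so it is
# assigned to the first-listed target (LSI-2 in both cases).
probe	target	n_blocks	region
CBR-1	LSI-3	1
CBR-1	LSI-5	1
CBR-1	LSI-6	1
CBR-1	LSI-7	1
CBR-2	LSI-2	2
CBR-2	LSI-4	1
CBR-2	LSI-8	1
CBR-2	LSI-9	1
CBR-3	LSI-1	1
CBR-3	LSI-7	1
CBR-3	LSI-10	1
CBR-4	LSI-1	1
CBR-4	LSI-8	1
CBR-5	LSI-4	1
CBR-5	LSI-15	1
CBR-6	LSI-12	1
CBR-6	LSI-16	1
CBR-7	LSI-11	1
CBR-8	LSI-13	1
CBR-9	LSI-14	1
CBR-X	LSI-X	1
CBR-Y2	LSI-2	2
CBR-Y2	LSI-6	1
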