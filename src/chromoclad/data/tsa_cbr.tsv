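# Painting of Carollia brevicauda (CBR) whole-chromosome probes on
# Tonatia saurophila (TSA): 31 homologous segments.
# CBR-4 gave three signals on TSA-3 and TSA-7, and CBR-2 five signals on
# TSA-1, 2, 4 and 5; the chromosome carrying the extra block is not named in
# either case, so it is assigned to the first-listed target (TSA-3, TSA-1).
# CBR-1's two discontiguous blocks are explicitly on TSA-6.
probe	target	n_blocks	region
CBR-1	TSA-1	1
CBR-1	TSA-2	1
CBR-1	TSA-4	1
CBR-1	TSA-6	2
CBR-2	TSA-1	2
CBR-2	TSA-2	1
CBR-2	TSA-4	1
CBR-2	TSA-5	1
CBR-3	TSA-2	1
CBR-3	TSA-3	1
CBR-3	TSA-4	1
CBR-3	TSA-7	1
CBR-4	TSA-3	2
CBR-4	TSA-7	1
CBR-5	TSA-4	1
CBR-5	TSA-7	1
CBR-6	TSA-1	1
CBR-6	TSA-2	1
CBR-6	TSA-5	1
CBR-7	TSA-5	1
CBR-8	TSA-1	1
CBR-8	TSA-5	1
CBR-9	TSA-6	1
CBR-X	TSA-X	1
CBR-Y2	TSA-1	1
CBR-Y2	TSA-2	1
CBR-Y2	TSA-3	1
CBR-Y2	TSA-5	1
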