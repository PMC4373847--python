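# Karyotype descriptions of the painted Phyllostomini species and the
# reference species Phyllostomus hastatus.  Morphologies of individual pairs
# beyond those explicitly described are recorded at the bi-armed/one-armed
# level needed for the FN arithmetic.
TSA:
  2n: 16
  fn: 20
  autosomes:
    - [TSA-1, bi_armed]
    - [TSA-2, bi_armed]
    - [TSA-3, bi_armed]
    - [TSA-4, one_armed]
    - [TSA-5, one_armed]
    - [TSA-6, one_armed]
    - [TSA-7, one_armed]
  sex:
    - [TSA-X, submetacentric]
    - [TSA-Y, acrocentric]
LSI:
  2n: 34
  fn: 60
  autosomes:
    - [LSI-1, bi_armed]
    - [LSI-2, bi_armed]
    - [LSI-3, bi_armed]
    - [LSI-4, bi_armed]
    - [LSI-5, bi_armed]
    - [LSI-6, bi_armed]
    - [LSI-7, bi_armed]
    - [LSI-8, bi_armed]
    - [LSI-9, bi_armed]
    - [LSI-10, bi_armed]
    - [LSI-11, bi_armed]
    - [LSI-12, bi_armed]
    - [LSI-13, bi_armed]
    - [LSI-14, bi_armed]
    - [LSI-15, acrocentric]
    - [LSI-16, acrocentric]
  sex:
    - [LSI-X, metacentric]
    - [LSI-Y, acrocentric]
PDI:
  2n: 32
  fn: 60
  autosomes:
    - [PDI-1, bi_armed]
    - [PDI-2, bi_armed]
    - [PDI-3, bi_armed]
    - [PDI-4, bi_armed]
    - [PDI-5, bi_armed]
    - [PDI-6, bi_armed]
    - [PDI-7, bi_armed]
    - [PDI-8, bi_armed]
    - [PDI-9, bi_armed]
    - [PDI-10, bi_armed]
    - [PDI-11, bi_armed]
    - [PDI-12, bi_armed]
    - [PDI-13, bi_armed]
    - [PDI-14, bi_armed]
    - [PDI-15, metacentric]
  sex:
    - [PDI-X, bi_armed]
    - [PDI-Y, acrocentric]
PHA:
  2n: 32
  fn: 58
  autosomes:
    - [PHA-1, bi_armed]
    - [PHA-2, bi_armed]
    - [PHA-3, bi_armed]
    - [PHA-4, bi_armed]
    - [PHA-5, bi_armed]
    - [PHA-6, bi_armed]
    - [PHA-7, bi_armed]
    - [PHA-8, bi_armed]
    - [PHA-9, bi_armed]
    - [PHA-10, bi_armed]
    - [PHA-11, bi_armed]
    - [PHA-12, bi_armed]
    - [PHA-13, bi_armed]
    - [PHA-14, bi_armed]
    - [PHA-15, acrocentric]
  sex:
    - [PHA-X, submetacentric]
    - [PHA-Y, acrocentric]
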