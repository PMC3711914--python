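# Default biogeographic partition for the wall-lizard dataset.
# Localities north/east of the Pyrenees, north of the Apennines, west/east of
# the Alps, and in the central Balkans are "northern"; localities inside the
# Iberian, Italian and Balkan refugial peninsulas are "southern"; everything
# else (e.g. Anatolia, outgroup sites) is unassigned and excluded from the
# origin tests.
northern: [1, 20, 21, 22, 23, 25, 26, 35, 36, 37, 38, 39]
southern: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 18,
           27, 28, 29, 30, 31, 32, 33, 34,
           40, 41, 42, 43, 44, 45, 46]
# Contiguous-southern reference sets: each northern block is also compared
# against the adjacent refugium only. Blocks 35-36 sit between the Italian
# and Balkan refugia and get both comparisons.
contiguous_blocks:
  - northern: [1]
    southern_sets:
      iberia: [2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 18]
  - northern: [20, 21, 22, 23, 25, 26]
    southern_sets:
      italy: [27, 28, 29, 30, 31, 32, 33, 34]
  - northern: [37, 38, 39]
    southern_sets:
      balkans: [40, 41, 42, 43, 44, 45, 46]
  - northern: [35, 36]
    southern_sets:
      italy: [27, 28, 29, 30, 31, 32, 33, 34]
      balkans: [40, 41, 42, 43, 44, 45, 46]
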