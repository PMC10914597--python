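# Default eight-slot modular-cloning grammar.
#
# Fusion-site overhangs follow the widely used S. cerevisiae modular yeast-
# toolkit convention so that parts remain compatible with existing yeast
# kits.  Slot 8 carries the vector body (bacterial origin + marker) and
# closes the ring back onto slot 1.  Slots 3 (CDS) and 4 (terminator) can be
# split into a/b halves for N-/C-terminal fusions.
name: default
enzymes:
  entry:    {name: BsmBI, recognition: CGTCTC, spacer_len: 1, overhang_len: 4}
  cassette: {name: BsaI,  recognition: GGTCTC, spacer_len: 1, overhang_len: 4}
slots:
  - {id: "1", role: assembly connector (left),  left: CCCT, right: AACG}
  - {id: "2", role: promoter,                   left: AACG, right: TATG}
  - {id: "3", role: coding sequence,            left: TATG, right: ATCC}
  - {id: "4", role: terminator,                 left: ATCC, right: GCTG}
  - {id: "5", role: assembly connector (right), left: GCTG, right: TACA}
  - {id: "6", role: yeast marker,               left: TACA, right: GAGT}
  - {id: "7", role: integration homology / ARS, left: GAGT, right: CCGA}
  - {id: "8", role: vector backbone (E. coli origin + marker), left: CCGA, right: CCCT}
splits:
  "3": ["3a", "3b"]
  "4": ["4a", "4b"]
split_slots:
  - {id: "3a", role: N-terminal fusion / tag, left: TATG, right: TTCT}
  - {id: "3b", role: coding sequence (core),  left: TTCT, right: ATCC}
  - {id: "4a", role: C-terminal fusion / tag, left: ATCC, right: TGGC}
  - {id: "4b", role: terminator (core),       left: TGGC, right: GCTG}
entry_overhangs: {left: AGCA, right: GCAA}
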