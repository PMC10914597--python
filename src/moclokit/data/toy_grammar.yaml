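# Miniature-kit grammar used by the deterministic toy-kit generator.
#
# It deliberately uses its own synthetic overhang set (distinct from the
# default grammar's) so that tests never depend on any real kit's fusion
# sites.  The ring has nine members: part slots 1..8 plus the destination-
# backbone slot "B" that closes the ring, so a complete Level 1 assembly
# contains nine fragments and nine junctions.
name: toy
enzymes:
  entry:    {name: BsmBI, recognition: CGTCTC, spacer_len: 1, overhang_len: 4}
  cassette: {name: BsaI,  recognition: GGTCTC, spacer_len: 1, overhang_len: 4}
slots:
  - {id: "1", role: assembly connector (left),  left: CCAA, right: AACG}
  - {id: "2", role: promoter,                   left: AACG, right: TATG}
  - {id: "3", role: coding sequence,            left: TATG, right: ATCC}
  - {id: "4", role: terminator,                 left: ATCC, right: GCTG}
  - {id: "5", role: assembly connector (right), left: GCTG, right: TACA}
  - {id: "6", role: yeast marker,               left: TACA, right: GAGT}
  - {id: "7", role: integration homology / ARS, left: GAGT, right: CCGA}
  - {id: "8", role: 3' spacer,                  left: CCGA, right: TGTC}
  - {id: "B", role: vector backbone (E. coli origin + marker), left: TGTC, right: CCAA}
splits:
  "3": ["3a", "3b"]
  "4": ["4a", "4b"]
split_slots:
  - {id: "3a", role: N-terminal fusion / tag, left: TATG, right: TTCT}
  - {id: "3b", role: coding sequence (core),  left: TTCT, right: ATCC}
  - {id: "4a", role: C-terminal fusion / tag, left: ATCC, right: TGGC}
  - {id: "4b", role: terminator (core),       left: TGGC, right: GCTG}
entry_overhangs: {left: CAGT, right: GTTC}
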