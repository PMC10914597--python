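# moclokit

An in-silico Golden Gate / MoClo toolkit for designing modular yeast
expression vectors, written for synthetic biologists building or using
*Komagataella phaffii* (Pichia) style cloning kits.

Golden Gate assembly uses Type IIS restriction endonucleases (BsaI, BsmBI)
that cut outside their recognition sites, leaving programmable 4-nt 5'
overhangs ("fusion sites"). The MoClo convention assigns every DNA element
to a *part type* — a slot in an assembly ring bounded by fixed fusion sites
— so that a one-pot digestion–ligation reaction assembles all parts
directionally into a single vector. `moclokit` simulates this exactly:

- **Grammar** — load/validate a part-type grammar (slots 1–8, splittable
  slots 3a/3b and 4a/4b, enzymes, entry overhangs) from YAML; a default
  eight-slot grammar and a miniature "toy" grammar ship with the package.
- **Digestion** — Type IIS digestion of linear and circular molecules with
  exact cut geometry. For a plus-strand site at position *r*,
  `cut_top = r + |recog| + spacer` and `cut_bottom = cut_top + 4`; every
  sticky end is identified by the top-strand 4-mer of the religated
  junction, so end compatibility is string equality.
- **Assembly** — enumerate all circular ligation products, keep only
  *stable* ones (zero residual sites of the active enzyme — the fixpoint of
  the final-digest step), and run the Level 0 → 1 → 2 hierarchy with
  grammar-conformance checks. Reaction stoichiometry helper:
  ng = fmol × bp × 650 × 10⁻⁶.
- **Fidelity** — score an overhang set from a pairwise ligation-frequency
  table: `fidelity(o) = t[o, wc(o)] / Σ_p t[o, wc(p)]` per junction,
  combined multiplicatively; a Watson–Crick-only table scores exactly 1.
- **Domestication** — remove internal BsaI/BsmBI sites from a CDS by
  deterministic synonymous codon substitution, and design synthesis-ready
  flanked fragments whose entry-vector round trip releases the typed part.
- **Strain-engineering design** — split-marker cassette design (default:
  first and last two-thirds of the marker, overlap ≈ L/3), Cre/lox
  direct-repeat excision leaving one 34-bp loxP scar, and
  frameshift-consequence prediction (mutant protein length, altered codons,
  premature-to-canonical stop distance).

A deterministic toy-kit generator builds a complete miniature kit (eight
Level 0 part plasmids + entry and destination backbones) from one seed, so
every simulation can be exercised without downloading anything.

## Worked example

```
$ moclokit simulate-kit --seed 1 --out kit
wrote parts: kit/parts.fasta
wrote entry_backbone: kit/entry_backbone.fasta

$ moclokit assemble --level 1 --parts kit --grammar toy --out expression_vector.gb
# moclokit 1.0.0 grammar=toy:708c19269a62
fragment        overhang  length_bp
part_1[183:37]  AACG      52
part_2[27:73]   TATG      46
...
destination_backbone[48:0]  CCAA  154
wrote expression_vector.gb (564 bp, 9 fragments)
```

The report lists the nine ring fragments (eight parts + backbone body) in
assembly order with the 4-nt overhang sealing each junction; the GenBank
output is circular and re-digests to zero BsaI sites. Domestication edits
the minimum number of codons and never changes the protein:

```
$ printf '>goi\nATGGCTGGTCTCGAAAAGTCTTAA\n' > goi.fa
$ moclokit domesticate --in goi.fa --out goi_dom.fa --grammar toy
goi: 1 codon(s) edited        # GGTCTC -> GGACTC, protein unchanged
```

Frameshift analysis on a CDS (`--pos` is the 1-based edited base):

```
$ moclokit frameshift --in goi_dom.fa --pos 7 --kind del --len 1
id   orig_aa  mutant_aa  fs_codon  altered_codons  premature_stop_nt  stop_distance_nt  in_frame
goi  7        7          3         4               -                  -                 no
```

Here the 1-bp deletion shifts the frame in codon 3; the shifted frame never
hits a stop (`-`), so the ORF is open-ended. On the shipped 1,191-bp
surrogate of the *HOC1* truncation allele, deleting base 755 reports a
274-aa mutant protein with 22 altered codons after the frameshift.

Other subcommands: `validate-grammar`, `classify`, `fidelity`, `flank`,
`splitmarker`, `excise`, `stoichiometry`.

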