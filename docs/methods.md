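# Methods

## Sequence model

Molecules are double-stranded DNA stored as the top strand 5'→3', strict
ACGT (IUPAC ambiguity is allowed only in enzyme recognition sequences,
where it is expanded during scanning). Coordinates are 0-based, half-open,
on the top strand; circular arithmetic is modulo the length, and
origin-spanning feature spans are written `start > end`. Product identity
for circular molecules is the lexicographically smallest rotation of the
top strand with ties broken at offset zero; the strand is never flipped,
because the backbone orientation fixes the frame of an assembly.

## Type IIS digestion

An enzyme is `(recognition, spacer_len, overhang_len)`. Only 5'-extension
cutters are modelled (both shipped enzymes produce 5' overhangs); the
overhang length must be ≥ 1, so blunt or 3'-overhang cutters are rejected
at construction. For a plus-strand recognition starting at `r`,
`cut_top = r + |recog| + spacer_len` and `cut_bottom = cut_top +
overhang_len`; minus-strand sites mirror this. Shipped reference
geometries: BsaI `GGTCTC(1/4)`, BsmBI `CGTCTC(1/4)`, BbsI `GAAGAC(2/4)`,
SapI `GCTCTTC(1/3)` — overridable in any grammar config.

`find_sites` reports every recognition occurrence on both strands;
circular molecules are scanned on a doubled sequence so origin-spanning
sites are found, and positions are deduplicated modulo the length. On
linear molecules a site whose cut window falls off an end is still
reported but cannot cut; `digest` skips it. Two sites cutting inside the
same overhang window make the fragment set ill-defined and raise an
ambiguity error rather than guessing.

A fragment's `core` is its physical top strand: it includes the 4-nt
left-junction bases (the 5' single-stranded extension) and excludes the
right-junction bases, which ride on the bottom strand. Concatenating cores
of consecutive fragments therefore reconstructs the source exactly, and
for a circular digestion the core lengths sum to the molecule length.
Every sticky end is identified by the top-strand 4-mer of the religated
junction, so two ends are compatible iff the strings are equal — the
standard fusion-site notation.

Annotation features are clipped and re-coordinated into each fragment;
features that describe a *previous* assembly (kinds `part`, `junction`,
`fragment`) are deliberately dropped on re-digestion, since the next
ligation writes fresh ones.

## Ligation and the level hierarchy

`ligate` enumerates every distinct circular chain of sticky fragments
(depth-first over the compatibility graph, each cycle counted once via its
minimal-index member, each fragment instance used at most once per
product), deduplicates by canonical rotation and returns a sorted list, so
the output is deterministic and invariant under input permutation and
rotation of circular inputs. The ring length is capped (default: the
number of fragments) to bound combinatorics. Misligation is off by
default — only exact 4-mer matches anneal, the regime a high-fidelity
overhang set is designed for; passing a ligation-frequency table relaxes
compatibility to pairs with positive cross-ligation frequency so
low-fidelity side products can be enumerated.

`golden_gate` digests every input, ligates, and keeps only *stable*
circles: zero residual recognition sites of the active enzyme on either
strand, which is the fixpoint enforced by the final digestion step of the
one-pot protocol. Unstable circles, uncut circular inputs, and dangling
overhangs (computed over the site-free fragments, whose left/right usage
counts must balance for a ring to close) are reported as diagnostics. The
thermocycling constants (>25 cycles of 42 °C/2 min digest and 16 °C/5 min
ligation for BsmBI, 37 °C digests for BsaI, 60 °C/10 min final digest,
80 °C/10 min inactivation) and the 20-fmol backbone stoichiometry are
carried as protocol metadata, not simulated kinetically.

`assemble_level` selects the enzyme by level (entry enzyme for Levels 0
and 2, cassette enzyme for Level 1), asserts exactly one stable product,
and checks that the product's fragment junctions traverse the grammar ring
in order. Level 2 is implemented generically: it is a Level-1-shaped
assembly over a second (connector) grammar instance with the entry enzyme,
rather than a special-cased pathway.

## Grammar

A grammar is an ordered ring of part types, each bounded by left/right
fusion sites; consecutive members share a junction and the last wraps to
the first. Splittable slots (3 → 3a+3b, 4 → 4a+4b) must partition their
parent: first child inherits the parent's left site, last child its right,
adjacent children share a junction. Validation reports (never raises)
broken rings, duplicate junction overhangs, palindromic
(self-complementary, hence self-ligating) overhangs and malformed split
rules.

The default grammar has eight slots with slot 8 as the vector-backbone
slot closing the ring; its fusion sites follow the widely used
*S. cerevisiae* modular yeast-toolkit convention for cross-kit
compatibility. The toy grammar used by the fixture generator has nine ring
members — part slots 1–8 plus a dedicated backbone slot `B` — so a full
Level 1 product contains nine fragments and nine junctions; it uses its
own synthetic overhang set so no test depends on any real kit's sequences.

## Ligation fidelity

The per-junction fidelity of overhang `o` against a reaction pool is the
normalised Watson–Crick fraction `t[o, wc(o)] / Σ_p t[o, wc(p)]`, where
`t` is a pairwise ligation-frequency table keyed by (overhang,
partner-as-top-strand-4-mer) and `wc` is the reverse complement. Missing
entries count as zero; a zero denominator is an explicit undefined-fidelity
error. Palindromic overhangs pick up their self-ligation term naturally,
since `wc(o) = o` then appears in the denominator. Junction fidelities
combine multiplicatively into the overall score, and enlarging the pool
can only grow denominators, so fidelity is monotone non-increasing in pool
size. The shipped default table is WC-only and uniform — an idealised
no-cross-talk model under which any valid set scores exactly 1.0; load an
empirical table for realistic estimates. Junctions under 0.95 (config
threshold) are flagged.

## Domestication and flank design

Domestication scans both strands of a CDS for forbidden recognition sites
and removes each by a synonymous single-codon substitution, with a fully
deterministic tie-break: sites left→right, codons within a site
left→right, synonymous replacements in lexicographic order, first
substitution that destroys the occurrence wins. The sequence is re-scanned
after each edit (a swap can create a new site), with an iteration cap to
guarantee termination; a site whose covering codons admit no synonymous
escape (e.g. Met/Trp-only windows) raises an error naming the stuck
position. Only the standard genetic code (table 1) is supported, and only
site removal — codon-usage optimisation for expression is out of scope.

A synthesis flank for slot *s* is laid out as: outward-cutting entry-enzyme
site exposing the entry-backbone overhang, inward-cutting cassette-enzyme
site exposing the slot's left fusion site, the core, then the mirror image
on the right. The spacer pads are chosen deterministically (A first, then
alternatives) so that the fragment contains exactly two sites of each
enzyme; a core that still carries a forbidden site is rejected with a
pointer to domestication. The round-trip property — Level 0 assembly then
cassette digestion releases exactly the typed part, core unchanged — is
tested for every slot including the split slots.

## Frameshift and stop-distance arithmetic

`frameshift_consequence` applies a 1-based insertion/deletion,
re-translates, and reports: `frameshift_codon = ceil(edit_pos / 3)`;
`altered_codons = mutant_protein_len − frameshift_codon` (floored at 0).
The codon containing the edit is counted as unaltered even if its residue
changes — this convention makes a 274-aa truncation product of an edit at
base 755 report 252 + 22, i.e. 22 altered codons, matching how such
alleles are described. Edits of length divisible by 3 are reported
in-frame with no frameshift. `stop_distance` counts the nucleotides
strictly between the last base of the premature stop (located by
translation) and the first base of the canonical stop (given in mutant
coordinates); it is invariant under edits upstream of the premature stop
because both positions shift together.

The shipped worked-example loci (`synthetic_loci.py`) are **synthetic
surrogates**, not genomic sequence: a 1,191-bp CDS whose poly-A stretch at
745–756 is built so a 1-bp deletion at position 755 frameshifts in codon
252 and truncates to 274 aa, and a truncated-allele locus with a
configurable premature-to-canonical stop separation (default 405 nt, so a
115-bp downstream deletion leaves 290 nt). Reconstructing the real
α-1,6-mannosyltransferase locus requires the published *K. phaffii*
reference assembly; note a 1,191-bp CDS yields a 396-aa protein
(1191/3 − 1), so the occasionally quoted 398-aa full-length figure cannot
be reproduced from that CDS length and is not asserted anywhere.

## Strain-edit design

`apply_edit` performs 1-based insertion/deletion/replacement with feature
re-coordination: features wholly inside a deletion are dropped, partial
overlaps are truncated and flagged. Homologous integration is composed
from replacement edits rather than modelling recombination. The
split-marker designer takes the first `ceil(f1·L)` and last `ceil(f2·L)`
bases of an L-nt marker (defaults: two-thirds each, overlap
`2·ceil(2L/3) − L ≈ L/3`); the suffix/prefix identity and
full-cassette reconstruction are enforced invariants, and a non-positive
overlap is a design error. Whether a particular published cassette's
overlap (e.g. 594 bp) equals the two-thirds default depends on the marker,
so the split fractions remain free parameters. Cre excision removes the
span between the first *direct-repeat* lox pair (top- or bottom-strand
orientation), leaving exactly one copy — hence idempotent; inverted-repeat
pairs raise an unsupported-operation error because inversion is not
modelled. The default lox sequence is the canonical 34-bp loxP.

## Toy kit

The fixture generator draws everything from one `random.Random(seed)`
stream (no global RNG): part cores are random ORFs of 30–60 nt (whole
codons, ATG start, sense codons), domesticated against both enzymes,
flanked, and cloned in silico into the entry backbone; backbones are
random stuffers around a dropout cassette. Collisions — accidental
junction-spanning recognition sites, non-unique closure — are detected by
digestion/assembly checks and resolved by redrawing from the same stream,
so generation is deterministic and total. The kit guarantees: every part
plasmid has exactly two cassette sites and zero entry sites; the nine
Level 1 inputs (eight part plasmids + destination backbone) produce
exactly one stable product that re-digests to nothing.

The kit emulates the *structure* of a real MoClo kit, not its content:
cores are abstract ORFs, not promoters/terminators/markers; lengths are
tens of bases rather than kilobases (the assembly algebra is
length-independent, which is why desk-scale sizes are used in tests and
the acceptance script); and ligation is all-or-nothing string matching, so
passing tests demonstrate the combinatorial correctness of the design
rules, not wet-lab yields, transformation efficiencies or fidelity under
real ligase kinetics.

## Numerical and convention choices

- Canonical-rotation ties break at the smallest offset; equal-sequence
  products deduplicate regardless of fragment provenance.
- Junction reports list each fragment with the overhang sealing its
  *right* junction.
- GenBank export converts to 1-based inclusive coordinates at the boundary
  and preserves circular topology; FASTA headers carry
  `type=`/`topology=` tokens but plain headers are accepted, with slot
  classification falling back to digestion-based inference.
- `fmol_to_ng` uses 650 g·mol⁻¹·bp⁻¹ (configurable).
- All CLI reports embed the tool version, a 12-hex-digit SHA-256 prefix of
  the grammar config, and the seed, making runs byte-reproducible.

## Known limitations

No methylation sensitivity, partial-digestion kinetics, thermodynamic
annealing model or enzyme star activity; no transformation-efficiency or
colony statistics; no SBOL export; alternative genetic codes unsupported;
lox inversion unmodelled. The acceptance script's 50-kit sweep and the
test suite's randomized property checks use fixed seeds, so they are
reproducible but sample only a slice of sequence space.
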