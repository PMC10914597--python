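"""Deterministic miniature MoClo kit generator.

The toy kit is a complete, self-consistent fixture: eight Level 0 part
plasmids (slots 1..8 of the toy grammar), an entry backbone and a
destination backbone, all generated from a single explicit seed.  Part cores
are random open reading frames, domesticated against both assembly enzymes
and wrapped by the synthesis-flank designer, then cloned in silico into the
entry backbone -- so generating a kit exercises the digestion, ligation,
domestication and flank-design machinery end to end.  Assembling all nine
Level 1 inputs (eight part plasmids plus the destination backbone) yields
exactly one stable expression vector.

Sequences are intentionally abstract (random cores, generic stuffers); the
kit makes no attempt to emulate real promoter or terminator sequences.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from .assembly import AssemblyProduct, assemble_level, golden_gate
from .codon import CODON_TO_AA, domesticate_cds, flank_part
from .errors import MoCloError
from .grammar import Grammar, toy_grammar
from .io_formats import write_fasta
from .seqcore import DnaMolecule, Feature, find_sites, revcomp_iupac

_SENSE_CODONS = sorted(CODON_TO_AA)


@dataclass
class ToyKit:
    """A complete miniature kit bound to the toy grammar."""

    grammar: Grammar
    part_plasmids: Dict[str, DnaMolecule]
    entry_backbone: DnaMolecule
    destination_backbone: DnaMolecule
    part_cores: Dict[str, str]
    seed: int

    def level1_inputs(self) -> List[DnaMolecule]:
        """The nine molecules of a full Level 1 reaction."""
        return [self.part_plasmids[s] for s in sorted(self.part_plasmids)] \
            + [self.destination_backbone]

    def assemble(self) -> AssemblyProduct:
        """Level 1 assembly of all parts into the destination backbone."""
        return assemble_level(self.part_plasmids, self.destination_backbone,
                              self.grammar, level=1)


def _random_orf(rng: random.Random, n_codons: int) -> str:
    return "ATG" + "".join(rng.choice(_SENSE_CODONS)
                           for _ in range(n_codons - 1))


def _clean_stuffer(rng: random.Random, length: int, g: Grammar) -> str:
    """Random sequence free of both enzymes' recognition sites."""
    for _ in range(200):
        s = "".join(rng.choice("ACGT") for _ in range(length))
        mol = DnaMolecule(s, name="stuffer")
        if not find_sites(mol, g.enzyme_entry) and \
                not find_sites(mol, g.enzyme_cassette):
            return s
    raise MoCloError("could not draw a site-free stuffer")  # pragma: no cover


def _backbone(g: Grammar, enzyme, dropout_left: str, dropout_right: str,
              body: str, filler: str, name: str) -> DnaMolecule:
    """Circular backbone whose digestion with ``enzyme`` releases a dropout
    (junctions dropout_left -> dropout_right) and the body (the converse)."""
    pad = "A" * enzyme.spacer_len
    seq = (dropout_left + pad + revcomp_iupac(enzyme.recognition)
           + filler
           + enzyme.recognition + pad + dropout_right
           + body)
    feats = [Feature("dropout", 0, len(seq) - len(body), "+", "misc_feature"),
             Feature("body", len(seq) - len(body), len(seq), "+", "misc_feature")]
    return DnaMolecule(seq, "circular", feats, name)


def generate_toy_kit(seed: int, core_len_range: Tuple[int, int] = (30, 60)
                     ) -> ToyKit:
    """Build the full toy kit from one seed; byte-reproducible.

    ``core_len_range`` bounds the part-core length in nt (rounded to whole
    codons, minimum 4 codons).  Cores colliding with enzyme sites after
    domestication, or kits whose Level 1 reaction does not close uniquely,
    are simply redrawn from the same stream -- generation never fails for
    benign collisions.
    """
    lo, hi = core_len_range
    if hi < lo or lo < 10:
        raise MoCloError("core_len_range must span at least 10 nt")
    rng = random.Random(seed)
    g = toy_grammar()
    E, C = g.enzyme_entry, g.enzyme_cassette

    def _checked_backbone(enzyme, other, dropout_left, dropout_right,
                          body_len, name):
        # redraw stuffers until the circle has exactly the two designed
        # sites of its own enzyme and none of the other (joints between
        # stuffers and fixed blocks can create accidental sites)
        for _ in range(50):
            bb = _backbone(g, enzyme, dropout_left, dropout_right,
                           body=_clean_stuffer(rng, body_len, g),
                           filler=_clean_stuffer(rng, 30, g), name=name)
            if len(find_sites(bb, enzyme)) == 2 and not find_sites(bb, other):
                return bb
        raise MoCloError(f"could not build {name}")  # pragma: no cover

    for _attempt in range(20):
        entry_backbone = _checked_backbone(E, C, g.entry_left, g.entry_right,
                                           120, "entry_backbone")
        bb_slot = g.backbone_slot
        destination_backbone = _checked_backbone(C, E, bb_slot.right,
                                                 bb_slot.left, 150,
                                                 "destination_backbone")

        parts: Dict[str, DnaMolecule] = {}
        cores: Dict[str, str] = {}
        part_slots = [p.slot_id for p in g.part_types
                      if p.slot_id != bb_slot.slot_id]
        ok = True
        for slot in part_slots:
            plasmid = None
            for _retry in range(50):
                n_codons = max(4, rng.randrange(lo, hi + 1) // 3)
                core = domesticate_cds(_random_orf(rng, n_codons), [E, C])
                try:
                    frag = flank_part(core, slot, g)
                    product = assemble_level({slot: frag}, entry_backbone,
                                             g, level=0)
                except MoCloError:
                    continue
                if len(find_sites(product.molecule, C)) != 2 or \
                        find_sites(product.molecule, E):
                    continue  # junction-spanning accidental site: redraw core
                plasmid = product.molecule
                plasmid.name = f"part_{slot}"
                parts[slot] = plasmid
                cores[slot] = core
                break
            if plasmid is None:  # pragma: no cover - vanishingly unlikely
                ok = False
                break
        if not ok:
            continue

        kit = ToyKit(g, parts, entry_backbone, destination_backbone,
                     cores, seed)
        result = golden_gate(kit.level1_inputs(), C)
        if len(result.products) == 1:
            return kit
    raise MoCloError("toy-kit generation failed to converge")  # pragma: no cover


def write_kit(kit: ToyKit, out_dir) -> Dict[str, str]:
    """Write the kit to ``out_dir``: a nine-entry part-library FASTA (eight
    part plasmids + destination backbone, i.e. the Level 1 inputs) and the
    entry backbone in its own file.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lib = kit.level1_inputs()
    tokens = {m.name: {"type": s} for s, m in kit.part_plasmids.items()}
    tokens["destination_backbone"] = {"type": kit.grammar.backbone_slot.slot_id}
    parts_path = out / "parts.fasta"
    write_fasta(lib, parts_path, extra_tokens=tokens)
    entry_path = out / "entry_backbone.fasta"
    write_fasta([kit.entry_backbone], entry_path)
    return {"parts": str(parts_path), "entry_backbone": str(entry_path)}
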