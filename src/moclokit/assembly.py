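"""Directional Golden Gate ligation and the Level 0 -> 1 -> 2 hierarchy.

``ligate`` enumerates every distinct circular product that can be chained
from sticky fragments by exact fusion-site matching (a ``right_junction``
anneals to an equal ``left_junction``).  ``golden_gate`` models the one-pot
digestion-ligation reaction with its final-digest fixpoint: only circles
with zero residual recognition sites of the active enzyme survive.

Misligation is off by default -- only exact overhang matches anneal, which
is the regime a well-designed high-fidelity overhang set targets.  Passing a
ligation-frequency table enables enumeration of low-fidelity side products.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, TYPE_CHECKING

from .errors import (AssemblyError, ExpansionError, GrammarMismatchError,
                     MoCloError)
from .grammar import Enzyme, Grammar, PartType, expand_slots
from .seqcore import (DnaMolecule, Feature, StickyFragment, canonical_rotation,
                      digest, find_sites, revcomp)

if TYPE_CHECKING:  # pragma: no cover
    from .fidelity import LigationTable

#: Average molar mass of one base pair of double-stranded DNA, g/mol.
BP_GRAMS_PER_MOLE = 650.0

#: Reaction-protocol constants emitted in reports (metadata, not simulated).
PROTOCOL_METADATA = {
    "backbone_amount_fmol": 20,
    "entry_assembly_insert_excess_fmol": 1000,
    "cassette_assembly_part_fmol": 20,
    "cycles": ">25",
    "digest_temp_C": {"BsmBI": 42, "BsaI": 37},
    "ligation_temp_C": 16,
    "ligation_minutes": 5,
    "final_digest": "60 C for 10 min",
    "heat_inactivation": "80 C for 10 min",
}


@dataclass
class Junction:
    """One assembled junction: the overhang joining two fragments."""

    overhang: str
    upstream: StickyFragment
    downstream: StickyFragment


@dataclass
class AssemblyProduct:
    """A circular ligation product in canonical rotation."""

    molecule: DnaMolecule
    fragments: List[StickyFragment]
    junctions: List[Junction]
    stable: Optional[bool] = None

    def __len__(self) -> int:
        return len(self.molecule)


@dataclass
class Diagnostics:
    """Side information from a Golden Gate run."""

    unstable_products: List[AssemblyProduct] = field(default_factory=list)
    uncut_inputs: List[DnaMolecule] = field(default_factory=list)
    dangling_overhangs: List[str] = field(default_factory=list)
    blunt_fragments: int = 0


@dataclass
class GoldenGateResult:
    """Stable products plus diagnostics; iterates over the products."""

    products: List[AssemblyProduct]
    diagnostics: Diagnostics

    def __iter__(self):
        return iter(self.products)

    def __len__(self) -> int:
        return len(self.products)


def _compatible(right: str, left: str, table: Optional["LigationTable"],
                min_freq: float) -> bool:
    if right == left:
        return True
    if table is not None:
        # annealing strand of the partner end presenting 'left' is wc(left)
        return table.get(right, revcomp(left)) > min_freq
    return False


def _chain_to_product(chain: Sequence[StickyFragment]) -> AssemblyProduct:
    seq_parts: List[str] = []
    feats: List[Feature] = []
    offset = 0
    for f in chain:
        seq_parts.append(f.core)
        feats.append(Feature(f.name, offset, offset + len(f.core),
                             "+", "fragment"))
        feats.append(Feature(f.left_junction, offset,
                             offset + len(f.left_junction), "+", "junction"))
        for sub in f.features:
            feats.append(Feature(sub.label, offset + sub.start,
                                 offset + sub.end, sub.strand, sub.kind,
                                 sub.note))
        offset += len(f.core)
    mol = DnaMolecule("".join(seq_parts), "circular", feats, "assembly")
    mol = canonical_rotation(mol)
    junctions = [Junction(chain[i].right_junction, chain[i],
                          chain[(i + 1) % len(chain)])
                 for i in range(len(chain))]
    return AssemblyProduct(mol, list(chain), junctions)


def ligate(frags: Sequence[StickyFragment], *, max_ring: Optional[int] = None,
           table: Optional["LigationTable"] = None,
           min_freq: float = 0.0) -> List[AssemblyProduct]:
    """Enumerate all distinct circular products of sticky-end chaining.

    Each fragment instance is used at most once per product; blunt ends are
    never joined.  Products are deduplicated by the canonical rotation of
    their top strand and returned sorted (length, then sequence), so the
    output is deterministic and independent of input order.  ``max_ring``
    caps the number of fragments per circle (default: all of them).
    """
    if not frags:
        raise AssemblyError("ligate: empty fragment list")
    sticky = [f for f in frags
              if f.left_junction is not None and f.right_junction is not None]
    n = len(sticky)
    cap = max_ring or n
    products: Dict[str, AssemblyProduct] = {}

    def record(chain: List[int]) -> None:
        prod = _chain_to_product([sticky[i] for i in chain])
        products.setdefault(prod.molecule.seq, prod)

    def extend(chain: List[int], used: set) -> None:
        last = sticky[chain[-1]]
        first = sticky[chain[0]]
        if _compatible(last.right_junction, first.left_junction, table, min_freq):
            record(chain)
        if len(chain) >= cap:
            return
        for j in range(chain[0] + 1, n):
            if j in used:
                continue
            if _compatible(last.right_junction, sticky[j].left_junction,
                           table, min_freq):
                used.add(j)
                chain.append(j)
                extend(chain, used)
                chain.pop()
                used.discard(j)

    for start in range(n):
        extend([start], {start})
    return sorted(products.values(), key=lambda p: (len(p), p.molecule.seq))


def golden_gate(inputs: Sequence[DnaMolecule], e: Enzyme, *,
                max_ring: Optional[int] = None,
                table: Optional["LigationTable"] = None) -> GoldenGateResult:
    """One-pot digest-ligate-redigest simulation.

    Every input is digested with ``e``; the resulting sticky fragments are
    chained into circles; only *stable* circles -- those with zero residual
    recognition sites of ``e`` on either strand, the fixpoint the final
    digestion step enforces -- are returned as products.  Unstable circles,
    uncut circular inputs and dangling overhangs are reported in the
    diagnostics.
    """
    if not inputs:
        raise AssemblyError("golden_gate: no input molecules")
    diags = Diagnostics()
    frags: List[StickyFragment] = []
    for m in inputs:
        d = digest(m, e)
        if d.uncut:
            diags.uncut_inputs.append(m)
        frags.extend(d.fragments)
    sticky = [f for f in frags
              if f.left_junction is not None and f.right_junction is not None]
    diags.blunt_fragments = len(frags) - len(sticky)

    all_products = ligate(frags, max_ring=max_ring, table=table) if sticky else []
    stable: List[AssemblyProduct] = []
    for p in all_products:
        p.stable = not find_sites(p.molecule, e)
        (stable if p.stable else diags.unstable_products).append(p)

    # dangling-overhang diagnosis over the site-free fragments (the ones a
    # stable circle could be built from): an overhang whose left and right
    # usages do not balance can never close a ring.
    clean = [f for f in sticky
             if not find_sites(DnaMolecule(f.core, name="frag"), e)]
    lefts: Dict[str, int] = {}
    rights: Dict[str, int] = {}
    for f in clean:
        lefts[f.left_junction] = lefts.get(f.left_junction, 0) + 1
        rights[f.right_junction] = rights.get(f.right_junction, 0) + 1
    for o in sorted(set(lefts) | set(rights)):
        if lefts.get(o, 0) != rights.get(o, 0):
            diags.dangling_overhangs.append(o)

    return GoldenGateResult(sorted(stable, key=lambda p: (len(p), p.molecule.seq)),
                            diags)


def _classify_fragment(f: StickyFragment, ring: Sequence[PartType]) -> Optional[str]:
    matches = [p.slot_id for p in ring
               if p.left == f.left_junction and p.right == f.right_junction]
    return matches[0] if len(matches) == 1 else None


def assemble_level(parts: Mapping[str, DnaMolecule], backbone: DnaMolecule,
                   g: Grammar, level: int) -> AssemblyProduct:
    """Run one hierarchy level and assert a unique, grammar-conformant product.

    Level 0 (entry cloning) and level 2 (multigene assembly) use the entry
    enzyme; level 1 (expression-vector assembly) uses the cassette enzyme.
    The single stable product is checked against the grammar ring starting at
    the first ring slot, and its fragment features are relabelled with their
    slot assignments.
    """
    if level not in (0, 1, 2):
        raise AssemblyError(f"unknown assembly level {level}")
    enzyme = g.enzyme_cassette if level == 1 else g.enzyme_entry

    if level == 0:
        if len(parts) != 1:
            raise AssemblyError("level 0 takes exactly one typed fragment")
        (slot, frag_mol), = parts.items()
        result = golden_gate([frag_mol, backbone], enzyme)
        if len(result.products) != 1:
            raise AssemblyError(
                f"level 0 assembly of slot {slot}: {len(result.products)} "
                f"stable products (need exactly 1); dangling overhangs: "
                f"{result.diagnostics.dangling_overhangs}", result.diagnostics)
        product = result.products[0]
        for f in product.molecule.features:
            if f.kind == "fragment" and f.label.startswith(frag_mol.name):
                f.label = f"part {slot}"
                f.kind = "part"
        return product

    slot_ids = [str(s) for s in parts]
    try:
        expanded = expand_slots(g, slot_ids + [g.backbone_slot.slot_id])
    except ExpansionError as exc:
        raise AssemblyError(f"invalid slot coverage: {exc}") from exc
    result = golden_gate(list(parts.values()) + [backbone], enzyme)
    if len(result.products) != 1:
        raise AssemblyError(
            f"level {level} assembly: {len(result.products)} stable products "
            f"(need exactly 1); dangling overhangs: "
            f"{result.diagnostics.dangling_overhangs}", result.diagnostics)
    product = result.products[0]

    slot_seq: List[Tuple[str, StickyFragment]] = []
    for f in product.fragments:
        slot = _classify_fragment(f, expanded)
        if slot is None:
            raise GrammarMismatchError(
                f"fragment {f.name} with junctions "
                f"({f.left_junction},{f.right_junction}) matches no slot",
                result.diagnostics)
        slot_seq.append((slot, f))
    ring_order = [p.slot_id for p in expanded]
    got = [s for s, _ in slot_seq]
    k = len(got)
    rotation_ok = any(got[i:] + got[:i] == ring_order for i in range(k))
    if not rotation_ok:
        raise GrammarMismatchError(
            f"fragment order {got} does not follow the grammar ring "
            f"{ring_order}", result.diagnostics)

    frag_slot = {f.name: s for s, f in slot_seq}
    for feat in product.molecule.features:
        if feat.kind == "fragment" and feat.label in frag_slot:
            feat.note = feat.label
            feat.label = f"part {frag_slot[feat.label]}"
            feat.kind = "part"
    return product


def fmol_to_ng(length_bp: float, amount_fmol: float,
               bp_mass: float = BP_GRAMS_PER_MOLE) -> float:
    """Convert a molar DNA amount to mass: ng = fmol x bp x 650 x 1e-6.

    650 g/mol/bp is the standard average for double-stranded DNA and can be
    overridden.  Used for reaction stoichiometry (e.g. 20 fmol of a 3 kb
    backbone = 39 ng).
    """
    if length_bp <= 0 or amount_fmol <= 0:
        raise MoCloError("fmol_to_ng: length and amount must be positive")
    return amount_fmol * length_bp * bp_mass * 1e-6
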