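"""Directional ligation, Golden Gate simulation and the level hierarchy."""

import itertools
import random

import pytest

from moclokit.assembly import (assemble_level, fmol_to_ng, golden_gate,
                               ligate)
from moclokit.errors import AssemblyError, MoCloError
from moclokit.seqcore import (DnaMolecule, StickyFragment, find_sites,
                              rotations)


def frag(core, left, right, name="f"):
    return StickyFragment(core, left, right, name, 0, len(core))


def brute_force_circles(frags):
    """Independent oracle: try every subset and ordering, keep closed rings,
    return the set of canonical top-strand sequences."""
    out = set()
    n = len(frags)
    for r in range(1, n + 1):
        for subset in itertools.permutations(range(n), r):
            chain = [frags[i] for i in subset]
            if any(c.left_junction is None or c.right_junction is None
                   for c in chain):
                continue
            ok = all(chain[i].right_junction == chain[(i + 1) % r].left_junction
                     for i in range(r))
            if ok:
                seq = "".join(c.core for c in chain)
                out.add(min(rotations(seq)))
    return out


class TestLigate:
    def test_two_fragment_closure(self):
        x = frag("AATGCCC", "AATG", "GCTT", "X")
        y = frag("GCTTGGG", "GCTT", "AATG", "Y")
        products = ligate([x, y])
        assert len(products) == 1
        assert products[0].molecule.seq == min(rotations("AATGCCCGCTTGGG"))
        assert [j.overhang for j in products[0].junctions] == ["GCTT", "AATG"]

    def test_self_circularization(self):
        s = frag("AATGCCCTTT", "AATG", "AATG", "S")
        products = ligate([s])
        assert len(products) == 1
        assert len(products[0].fragments) == 1

    def test_incompatible_ends_no_product(self):
        x = frag("AATGCCC", "AATG", "GCTT", "X")
        y = frag("TTCTGGG", "TTCT", "AATG", "Y")
        assert ligate([x, y]) == []

    def test_blunt_never_joined(self):
        x = frag("AAAA", None, "GCTT", "X")
        y = frag("GCTTCC", "GCTT", None, "Y")
        assert ligate([x, y]) == []

    def test_empty_input_is_error(self):
        with pytest.raises(AssemblyError):
            ligate([])

    def test_agrees_with_brute_force_oracle_up_to_six_fragments(self):
        rng = random.Random(7)
        overhangs = ["AATG", "GCTT", "TTCT", "CCAA"]
        for _ in range(40):
            n = rng.randrange(1, 7)
            frags = []
            for i in range(n):
                left, right = rng.choice(overhangs), rng.choice(overhangs)
                core = left + "".join(rng.choice("ACGT") for _ in range(6))
                frags.append(frag(core, left, right, f"f{i}"))
            got = {p.molecule.seq for p in ligate(frags)}
            assert got == brute_force_circles(frags)


class TestGoldenGate:
    def test_toy_kit_single_stable_product(self, kit):
        result = golden_gate(kit.level1_inputs(), kit.grammar.enzyme_cassette)
        assert len(result.products) == 1
        product = result.products[0]
        assert product.stable
        assert find_sites(product.molecule, kit.grammar.enzyme_cassette) == []

    def test_missing_slot_yields_dangling_overhangs(self, kit):
        g = kit.grammar
        inputs = [m for s, m in kit.part_plasmids.items() if s != "5"] \
            + [kit.destination_backbone]
        result = golden_gate(inputs, g.enzyme_cassette)
        assert result.products == []
        assert set(result.diagnostics.dangling_overhangs) == \
            {g.slot("5").left, g.slot("5").right}

    def test_invariant_under_input_permutation_and_rotation(self, kit):
        g = kit.grammar
        inputs = kit.level1_inputs()
        baseline = golden_gate(inputs, g.enzyme_cassette).products[0]
        shuffled = list(reversed(inputs))
        rotated = [DnaMolecule(m.seq[17:] + m.seq[:17], "circular", [], m.name)
                   for m in shuffled]
        alt = golden_gate(rotated, g.enzyme_cassette).products[0]
        assert alt.molecule.seq == baseline.molecule.seq

    def test_stable_product_redigests_to_nothing(self, kit):
        product = kit.assemble()
        d = find_sites(product.molecule, kit.grammar.enzyme_cassette)
        assert d == []


class TestAssembleLevel:
    def test_level1_ring_order(self, kit):
        product = kit.assemble()
        assert len(product.fragments) == 9
        part_labels = [f.label for f in product.molecule.features
                       if f.kind == "part"]
        assert sorted(part_labels) == sorted(
            f"part {p.slot_id}" for p in kit.grammar.part_types)

    def test_level0_releases_typed_part(self, kit):
        from moclokit.seqcore import digest
        g = kit.grammar
        plasmid = kit.part_plasmids["2"]
        d = digest(plasmid, g.enzyme_cassette)
        pairs = {(f.left_junction, f.right_junction) for f in d}
        assert (g.slot("2").left, g.slot("2").right) in pairs

    def test_missing_slot_is_assembly_error(self, kit):
        parts = {s: m for s, m in kit.part_plasmids.items() if s != "2"}
        with pytest.raises(AssemblyError):
            assemble_level(parts, kit.destination_backbone, kit.grammar, 1)


class TestStoichiometry:
    @pytest.mark.parametrize("bp,fmol,ng", [(3000, 20, 39.0), (1000, 1, 0.65)])
    def test_examples(self, bp, fmol, ng):
        assert fmol_to_ng(bp, fmol) == pytest.approx(ng)

    @pytest.mark.parametrize("bp,fmol", [(1, 0), (0, 20), (-5, 1)])
    def test_non_positive_rejected(self, bp, fmol):
        with pytest.raises(MoCloError):
            fmol_to_ng(bp, fmol)
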