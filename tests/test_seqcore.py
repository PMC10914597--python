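"""Sequence model and Type IIS digestion."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moclokit.errors import DigestionError, SequenceError
from moclokit.seqcore import (DnaMolecule, canonical_rotation, digest,
                              find_sites, revcomp, rotations)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestRevcomp:
    def test_examples(self):
        assert revcomp("") == ""
        assert revcomp("AATG") == "CATT"

    @given(dna)
    @settings(deadline=None)
    def test_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_rejects_non_acgt(self):
        with pytest.raises(SequenceError):
            revcomp("AANG")


class TestDnaMolecule:
    def test_canonicalizes_uppercase(self):
        m = DnaMolecule("acgt")
        assert m.seq == "ACGT"

    @pytest.mark.parametrize("bad", ["", "ACGN", "ACGU", "AC-GT"])
    def test_rejects_invalid(self, bad):
        with pytest.raises(SequenceError):
            DnaMolecule(bad)


def brute_force_sites(seq, recog, circular):
    """Independent oracle: scan seq+seq on both strands, dedupe modulo length."""
    hits = set()
    scan = seq + seq if circular else seq
    for strand, pat in (("+", recog), ("-", revcomp(recog))):
        for i in range(len(scan) - len(pat) + 1):
            if scan[i:i + len(pat)] == pat:
                pos = i % len(seq) if circular else i
                if not circular or i < len(seq):
                    hits.add((pos, strand))
    return hits


class TestFindSites:
    def test_linear_single_plus_site(self, bsai):
        m = DnaMolecule("AAAGGTCTCTAAA")
        sites = find_sites(m, bsai)
        assert [(s.strand, s.recog_start) for s in sites] == [("+", 3)]

    def test_no_sites(self, bsai):
        assert find_sites(DnaMolecule("AAAAAA"), bsai) == []

    def test_circular_origin_spanning_site(self, bsmbi):
        # CGTCTC spans the origin of this circle
        m = DnaMolecule("TCTCAAAAAAAACG", "circular")
        sites = find_sites(m, bsmbi)
        assert len(sites) == 1 and sites[0].strand == "+"
        assert sites[0].recog_start == 12

    def test_cut_geometry(self, bsai):
        # GGTCTC(1/5): top cut 1 nt after the recognition, 4-nt 5' overhang
        m = DnaMolecule("GGTCTCAAATGCCC")
        (s,) = find_sites(m, bsai)
        assert (s.cut_top, s.cut_bottom) == (7, 11)
        assert m.seq[s.cut_top:s.cut_bottom] == "AATG"

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_matches_brute_force_oracle(self, bsai, topology):
        rng = random.Random(42)
        for _ in range(25):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randrange(12, 80)))
            seq = seq[:5] + "GGTCTC" + seq[5:]  # plant at least one site
            m = DnaMolecule(seq, topology)
            got = {(s.recog_start, s.strand) for s in find_sites(m, bsai)}
            assert got == brute_force_sites(seq, "GGTCTC", topology == "circular")

    def test_mirror_on_reverse_complement(self, bsai):
        seq = "TTGGTCTCAAATGACCAGAGACCTT"
        m = DnaMolecule(seq)
        mirror = DnaMolecule(revcomp(seq))
        fwd = {(s.recog_start, s.strand) for s in find_sites(m, bsai)}
        rev = {(len(seq) - s.recog_start - 6,
                "+" if s.strand == "-" else "-")
               for s in find_sites(mirror, bsai)}
        assert fwd == rev


class TestDigest:
    def test_linear_three_fragments(self, bsai):
        seq = "GGTCTCA" + "AATG" + "CCCGGG" + "GCTT" + "TGAGACC"
        frags = digest(DnaMolecule(seq, name="ex"), bsai)
        assert len(frags) == 3
        left, mid, right = frags
        assert left.blunt_left and left.right_junction == "AATG"
        assert mid.core.startswith("AATG")
        assert (mid.left_junction, mid.right_junction) == ("AATG", "GCTT")
        assert right.left_junction == "GCTT" and right.blunt_right
        # conservation: concatenated cores reconstruct the source
        assert "".join(f.core for f in frags) == seq

    def test_linear_no_site_is_blunt_identity(self, bsai):
        frags = digest(DnaMolecule("AAAA"), bsai)
        assert len(frags) == 1
        assert frags[0].core == "AAAA"
        assert frags[0].blunt_left and frags[0].blunt_right

    def test_circular_uncut_distinguishable(self, bsai):
        d = digest(DnaMolecule("AAAAAAAAAA", "circular"), bsai)
        assert d.uncut and len(d) == 0

    def test_circular_part_plasmid_two_fragments(self, kit):
        enzyme = kit.grammar.enzyme_cassette
        for plasmid in kit.part_plasmids.values():
            d = digest(plasmid, enzyme)
            assert len(d) == 2
            assert sum(len(f.core) for f in d) == len(plasmid)

    def test_overlapping_cut_windows_raise(self, bsai):
        # + site cuts [7,11); - site (GAGACC at 13) cuts [8,12): ambiguous
        seq = "GGTCTC" + "A" + "ACGTAC" + "GAGACC"
        with pytest.raises(DigestionError):
            digest(DnaMolecule(seq), bsai)

    def test_rotation_invariance(self, kit):
        enzyme = kit.grammar.enzyme_cassette
        plasmid = kit.part_plasmids["3"]
        rot_seq = plasmid.seq[100:] + plasmid.seq[:100]
        rot = DnaMolecule(rot_seq, "circular", name="rot")
        cores = {f.core for f in digest(plasmid, enzyme)}
        cores_rot = {f.core for f in digest(rot, enzyme)}
        assert cores == cores_rot


class TestCanonicalRotation:
    def test_examples(self):
        assert canonical_rotation(DnaMolecule("GCA", "circular")).seq == "AGC"
        assert canonical_rotation(DnaMolecule("AAAA", "circular")).seq == "AAAA"

    def test_linear_rejected(self):
        with pytest.raises(SequenceError):
            canonical_rotation(DnaMolecule("ACGT"))

    @given(dna, st.integers(min_value=0, max_value=59))
    @settings(deadline=None)
    def test_invariant_under_prerotation(self, s, k):
        k %= len(s)
        m = DnaMolecule(s, "circular")
        pre = DnaMolecule(s[k:] + s[:k], "circular")
        expected = min(rotations(s.upper()))
        assert canonical_rotation(m).seq == expected
        assert canonical_rotation(pre).seq == expected
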