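"""Translation, domestication, flank design and frameshift arithmetic."""

import random

import pytest
from Bio.Seq import Seq

from moclokit.codon import (AA_TO_CODONS, domesticate_cds, flank_part,
                            frameshift_consequence, stop_distance, translate)
from moclokit.errors import (DomesticationError, FlankDesignError,
                             FrameshiftError, TranslationError)
from moclokit.grammar import Enzyme
from moclokit.seqcore import digest, find_sites
from moclokit.synthetic_loci import (canonical_stop_pos, synthetic_hoc1_cds,
                                     synthetic_truncated_locus)

SENSE = sorted(c for codons in AA_TO_CODONS.values() for c in codons)


class TestTranslate:
    def test_examples(self):
        assert translate("ATGAAATAA") == ("MK", True)
        assert translate("ATGTGA") == ("M", True)

    def test_open_ended_flagged(self):
        assert translate("ATGAAA") == ("MK", False)

    def test_errors(self):
        with pytest.raises(TranslationError):
            translate("AT")
        with pytest.raises(TranslationError):
            translate("ATGNNNTAA")

    def test_agrees_with_independent_codon_table_oracle(self):
        rng = random.Random(11)
        cds = "ATG" + "".join(rng.choice(SENSE) for _ in range(299)) + "TAA"
        mine = translate(cds)
        oracle = str(Seq(cds).translate(table=1, to_stop=True))
        assert mine.protein == oracle and mine.stopped


class TestDomesticate:
    def test_single_site_one_codon_edit(self, bsai):
        out = domesticate_cds("ATGGGTCTCTAA", [bsai])
        assert translate(out).protein == "MGL"
        assert "GGTCTC" not in out and "GAGACC" not in out
        edits = sum(out[i:i + 3] != "ATGGGTCTCTAA"[i:i + 3]
                    for i in range(0, 12, 3))
        assert edits == 1

    def test_clean_cds_unchanged(self, bsai, bsmbi):
        cds = "ATGAAACCCGAATAA"
        assert domesticate_cds(cds, [bsai, bsmbi]) == cds

    def test_bottom_strand_site_also_removed(self, bsai):
        # GAGACC on the top strand is a bottom-strand recognition
        cds = "ATG" + "GAGACC" + "TAA"
        out = domesticate_cds(cds, [bsai])
        assert "GAGACC" not in out and "GGTCTC" not in out
        assert translate(out).protein == translate(cds).protein

    def test_stuck_site_reported(self):
        # recognition spanning Met+Trp codons: no synonymous escape exists
        enzyme = Enzyme("MWcutter", "ATGTGG", 1, 4)
        with pytest.raises(DomesticationError) as exc:
            domesticate_cds("ATGTGGGCTGCTGCTTAA", [enzyme])
        assert exc.value.stuck_sites

    def test_randomized_planted_sites(self, bsai, bsmbi):
        rng = random.Random(5)
        for _ in range(40):
            n = rng.randrange(20, 60)
            codons = [rng.choice(SENSE) for _ in range(n)]
            cds = "ATG" + "".join(codons) + "TAA"
            # plant a recognition site at a random codon boundary
            k = 3 * rng.randrange(2, n - 2)
            site = rng.choice(["GGTCTC", "CGTCTC", "GAGACC", "GAGACG"])
            cds = cds[:k] + site + cds[k + 6:]
            try:
                out = domesticate_cds(cds, [bsai, bsmbi])
            except DomesticationError:
                continue  # legitimately stuck (planted site hit a Met/Trp run)
            assert translate(out) == translate(cds)
            for pat in ("GGTCTC", "CGTCTC", "GAGACC", "GAGACG"):
                assert pat not in out


class TestFlankPart:
    def test_site_counts(self, tg):
        core = domesticate_cds("ATGGCTGAAGCTGAATCTTAA",
                               [tg.enzyme_entry, tg.enzyme_cassette])
        mol = flank_part(core, "3b", tg)
        assert len(find_sites(mol, tg.enzyme_entry)) == 2
        assert len(find_sites(mol, tg.enzyme_cassette)) == 2

    def test_empty_core_rejected(self, tg):
        with pytest.raises(FlankDesignError):
            flank_part("", "3", tg)

    def test_undomesticated_core_rejected(self, tg):
        with pytest.raises(FlankDesignError):
            flank_part("ATGGGTCTCTAA", "3", tg)

    def test_round_trip_releases_typed_part(self, tg, kit):
        core = domesticate_cds("ATGGCTGAAGCTGAATCTTAA",
                               [tg.enzyme_entry, tg.enzyme_cassette])
        from moclokit.assembly import assemble_level
        frag = flank_part(core, "3b", tg)
        entry = assemble_level({"3b": frag}, kit.entry_backbone, tg, 0)
        released = [f for f in digest(entry.molecule, tg.enzyme_cassette)
                    if (f.left_junction, f.right_junction)
                    == (tg.slot("3b").left, tg.slot("3b").right)]
        assert len(released) == 1
        assert released[0].core == tg.slot("3b").left + core


class TestFrameshift:
    def test_hand_checked_deletion(self):
        r = frameshift_consequence("ATGAAAGTAAGGTGA", 7, "del", 1)
        assert r.mutant_protein_len == 2
        assert r.frameshift_codon == 3
        assert r.altered_codons == 0
        assert r.premature_stop_cds_pos == 7

    def test_in_frame_deletion_never_frameshifts(self):
        cds = "ATG" + "GCT" * 10 + "TAA"
        r = frameshift_consequence(cds, 4, "del", 3)
        assert r.in_frame and r.frameshift_codon is None
        assert r.mutant_protein_len == r.original_protein_len - 1

    def test_synthetic_hoc1_truncation_arithmetic(self):
        r = frameshift_consequence(synthetic_hoc1_cds(), 755, "del", 1)
        assert r.original_protein_len == 396
        assert r.mutant_protein_len == 274
        assert r.frameshift_codon == 252
        assert r.altered_codons == 22

    def test_insertion_then_deletion_identity(self):
        # edit downstream of the stop so both sequences stay translatable
        cds = "ATGTAAACC"
        r = frameshift_consequence(cds, 7, "ins", 1, payload="G")
        assert r.mutant_cds == "ATGTAAGACC"
        back = frameshift_consequence(r.mutant_cds, 7, "del", 1)
        assert back.mutant_cds == cds

    def test_edit_beyond_end_rejected(self):
        with pytest.raises(FrameshiftError):
            frameshift_consequence("ATGTAA", 99, "del", 1)


class TestStopDistance:
    def test_definition(self):
        loc = synthetic_truncated_locus(405)
        assert stop_distance(loc.seq, canonical_stop_pos(loc)) == 405

    def test_downstream_deletion_shortens_distance(self):
        from moclokit.strainedit import Edit, apply_edit
        loc = synthetic_truncated_locus(405)
        prem_end = next(f.end for f in loc.features
                        if f.label == "premature stop")
        edited = apply_edit(loc, Edit("deletion", pos=prem_end + 1, length=115))
        assert stop_distance(edited.seq, canonical_stop_pos(edited)) == 290

    def test_invariant_under_upstream_edit(self):
        from moclokit.strainedit import Edit, apply_edit
        loc = synthetic_truncated_locus(99)
        # a 3-nt deletion upstream of the premature stop shifts both stops
        edited = apply_edit(loc, Edit("deletion", pos=4, length=3))
        assert stop_distance(edited.seq, canonical_stop_pos(edited)) == 99

    def test_no_premature_stop_is_error(self):
        with pytest.raises(FrameshiftError):
            stop_distance("ATGAAATAA", 7)
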