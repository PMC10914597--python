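"""Translation, codon-aware domestication and frameshift analysis.

Domestication removes internal Type IIS recognition sites from a coding
sequence by synonymous codon substitution so the part can be carried through
Golden Gate assembly without being cut.  The scan is strand-agnostic and the
tie-break is fully deterministic: sites left to right, codons within a site
left to right, synonymous replacements in lexicographic order, first success
wins.

Frameshift analysis applies an insertion or deletion to a CDS, re-translates,
and reports the truncation arithmetic: mutant protein length, the 1-based
codon containing the first edited base, the number of altered codons
(``mutant_protein_len - frameshift_codon``, counting the codon containing
the edit as unaltered), and the distance between the premature and canonical
stop codons.  The standard genetic code (translation table 1) is used
throughout.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .errors import (DomesticationError, FlankDesignError, FrameshiftError,
                     TranslationError)
from .grammar import Enzyme, Grammar
from .seqcore import DnaMolecule, Feature, find_sites, iupac_regex, revcomp_iupac

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)

#: codon -> amino acid (one-letter), standard code, stops excluded
CODON_TO_AA: Dict[str, str] = dict(_TABLE.forward_table)

#: amino acid -> lexicographically sorted synonymous codons
AA_TO_CODONS: Dict[str, List[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)


class Translation(NamedTuple):
    """Peptide up to (excluding) the first stop, and whether one was reached."""

    protein: str
    stopped: bool


def translate(cds: str) -> Translation:
    """Translate from position 1 to the first stop codon (stop excluded).

    Trailing bases that do not fill a codon are ignored; a sequence with no
    stop codon is flagged ``stopped=False`` (open-ended ORF).
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise TranslationError("CDS shorter than one codon")
    if not re.fullmatch(r"[ACGT]+", cds):
        raise TranslationError("CDS must be strict ACGT")
    aas: List[str] = []
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            return Translation("".join(aas), True)
        aas.append(CODON_TO_AA[codon])
    return Translation("".join(aas), False)


def _site_occurrences(seq: str, enzymes: Sequence[Enzyme]) -> List[tuple]:
    """(start, end, enzyme-name, strand) of every recognition occurrence."""
    occ = []
    for e in enzymes:
        for strand, pat in (("+", e.recognition), ("-", revcomp_iupac(e.recognition))):
            for m in iupac_regex(pat).finditer(seq):
                occ.append((m.start(), m.start() + len(e.recognition),
                            e.name, strand))
    return sorted(occ)


def domesticate_cds(cds: str, forbidden: Sequence[Enzyme]) -> str:
    """Remove every internal forbidden recognition site by synonymous swaps.

    The translation of the output is identical to the input's and the edit is
    greedy-minimal (one codon per site where possible).  Unremovable sites
    (e.g. inside Met/Trp-only windows) raise :class:`DomesticationError`
    listing the stuck positions.
    """
    if not forbidden:
        raise DomesticationError("no forbidden enzymes given")
    cds = cds.upper()
    original = translate(cds)
    seq = cds
    max_rounds = len(_site_occurrences(seq, forbidden)) * 3 + 10
    for _ in range(max_rounds):
        occ = _site_occurrences(seq, forbidden)
        if not occ:
            return seq
        start, end, ename, _strand = occ[0]
        first_codon = start // 3
        last_codon = min((end - 1) // 3, len(seq) // 3 - 1)
        fixed = None
        for ci in range(first_codon, last_codon + 1):
            cur = seq[ci * 3: ci * 3 + 3]
            if len(cur) < 3:
                continue
            aa = CODON_TO_AA.get(cur)
            if aa is None:  # stop codon inside scan window; leave untouched
                continue
            for alt in AA_TO_CODONS[aa]:
                if alt == cur:
                    continue
                trial = seq[:ci * 3] + alt + seq[ci * 3 + 3:]
                window_lo = max(0, start - 12)
                window_hi = min(len(trial), end + 12)
                if any(s < end and e > start
                       for s, e, _, _ in _site_occurrences(
                           trial[window_lo:window_hi], forbidden)
                       for s, e in [(s + window_lo, e + window_lo)]):
                    continue
                fixed = trial
                break
            if fixed:
                break
        if fixed is None:
            raise DomesticationError(
                f"site {ename} at {start} not removable synonymously",
                stuck_sites=[(start, ename)])
        seq = fixed
    raise DomesticationError("domestication did not converge",
                             stuck_sites=[(s, n) for s, _, n, _ in
                                          _site_occurrences(seq, forbidden)])


def _pad(n: int, letter: str = "A") -> str:
    return letter * n


def flank_part(core: str, slot: str, g: Grammar) -> DnaMolecule:
    """Design the synthesis-ready linear fragment for one typed part.

    Layout (left to right): outward-cutting entry-enzyme site exposing the
    entry-backbone overhang, inward-cutting cassette-enzyme site exposing the
    slot's left overhang, the core, then the mirror image on the right.
    Entry-enzyme digestion plus entry-backbone ligation yields the Level 0
    plasmid; cassette digestion of that plasmid releases the core flanked by
    the slot's left/right overhangs.
    """
    core = str(core).upper()
    if not core:
        raise FlankDesignError("empty core")
    internal = find_sites(DnaMolecule(core, name="core"), g.enzyme_entry) + \
        find_sites(DnaMolecule(core, name="core"), g.enzyme_cassette)
    if internal:
        raise FlankDesignError(
            f"core contains {len(internal)} forbidden site(s); run "
            "domesticate_cds first")
    pt = g.slot(slot)
    E, C = g.enzyme_entry, g.enzyme_cassette

    for pads in itertools.product("ACGT", repeat=4):
        seq = (E.recognition + _pad(E.spacer_len, pads[0]) + g.entry_left
               + C.recognition + _pad(C.spacer_len, pads[1]) + pt.left
               + core
               + pt.right + _pad(C.spacer_len, pads[2]) + revcomp_iupac(C.recognition)
               + g.entry_right + _pad(E.spacer_len, pads[3]) + revcomp_iupac(E.recognition))
        mol = DnaMolecule(seq, "linear", name=f"part_{pt.slot_id}_synthesis")
        if (len(find_sites(mol, E)) == 2 and len(find_sites(mol, C)) == 2):
            off = len(E.recognition) + E.spacer_len + len(g.entry_left) \
                + len(C.recognition) + C.spacer_len + len(pt.left)
            mol.features.append(Feature(f"core {pt.slot_id}", off,
                                        off + len(core), "+", "part-core"))
            return mol
    raise FlankDesignError(
        f"could not place flanks around core for slot {slot} without "
        "creating stray recognition sites")


@dataclass
class FrameshiftReport:
    """Consequence of an insertion/deletion on an ORF."""

    original_protein_len: int
    mutant_protein_len: int
    frameshift_codon: Optional[int]
    altered_codons: int
    premature_stop_cds_pos: Optional[int]
    stop_distance_nt: Optional[int]
    in_frame: bool
    mutant_cds: str


def frameshift_consequence(cds: str, edit_pos: int, edit: str,
                           edit_len: int = 1,
                           payload: Optional[str] = None) -> FrameshiftReport:
    """Apply a del/ins to a CDS and report the truncation arithmetic.

    ``edit_pos`` is 1-based; a deletion removes ``edit_len`` bases starting
    there, an insertion places ``payload`` (default poly-A of ``edit_len``)
    before it.  Edits whose length is a multiple of 3 are reported in-frame
    with no frameshift.
    """
    cds = cds.upper()
    orig = translate(cds)
    if not orig.stopped:
        raise FrameshiftError("CDS has no canonical stop codon")
    if edit_pos < 1 or edit_pos > len(cds):
        raise FrameshiftError(f"edit position {edit_pos} outside CDS")
    if edit == "del":
        if edit_pos - 1 + edit_len > len(cds):
            raise FrameshiftError("deletion extends beyond sequence end")
        mutant = cds[:edit_pos - 1] + cds[edit_pos - 1 + edit_len:]
        shift = -edit_len
    elif edit == "ins":
        ins = (payload or "A" * edit_len).upper()
        if len(ins) != edit_len:
            raise FrameshiftError("payload length does not match edit_len")
        mutant = cds[:edit_pos - 1] + ins + cds[edit_pos - 1:]
        shift = edit_len
    else:
        raise FrameshiftError(f"unknown edit kind {edit!r}")

    mut = translate(mutant)
    in_frame = edit_len % 3 == 0
    fs_codon = None if in_frame else math.ceil(edit_pos / 3)
    altered = 0 if in_frame else max(0, len(mut.protein) - fs_codon)

    premature_pos = None
    distance = None
    if mut.stopped and not in_frame:
        premature_pos = 3 * len(mut.protein) + 1
        canonical_mut = 3 * len(orig.protein) + 1 + shift
        d = canonical_mut - (premature_pos + 2) - 1
        if d >= 0:
            distance = d
    return FrameshiftReport(len(orig.protein), len(mut.protein), fs_codon,
                            altered, premature_pos, distance, in_frame, mutant)


def stop_distance(cds_mutant: str, canonical_stop_pos: int) -> int:
    """Nucleotides strictly between the premature and canonical stop codons.

    ``canonical_stop_pos`` is the 1-based position of the first base of the
    canonical stop in mutant coordinates; the premature stop is located by
    translation.  Raises :class:`FrameshiftError` when there is no premature
    stop upstream of the canonical one.
    """
    t = translate(cds_mutant)
    if not t.stopped:
        raise FrameshiftError("no stop codon in mutant CDS")
    premature_last = 3 * len(t.protein) + 3  # 1-based last base of stop codon
    d = canonical_stop_pos - premature_last - 1
    if d < 0:
        raise FrameshiftError("no premature stop upstream of the canonical stop")
    return d
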