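"""Double-stranded sequence model and Type IIS digestion.

Molecules are stored as the top strand read 5'->3'.  Coordinates are 0-based,
half-open, on the top strand; circular arithmetic is modulo the length.  Every
sticky end is identified by the 4-mer (more generally, ``overhang_len``-mer)
that appears on the *top strand of the re-ligated junction*, so two ends are
compatible iff a ``right_junction`` string equals a ``left_junction`` string.

Only enzymes producing 5' extensions are modelled; both shipped enzymes
(BsaI, BsmBI) do.  For a recognition site on the plus strand starting at
``r`` the top-strand cut falls at ``r + len(recog) + spacer`` and the bottom
strand cut ``overhang_len`` further right; minus-strand sites mirror this.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Iterator, List, Optional, Sequence

from .errors import DigestionError, SequenceError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .grammar import Enzyme

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC nucleotide codes, used for enzyme recognition sequences only.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a strict-ACGT top strand."""
    if not re.fullmatch(r"[ACGT]*", seq):
        raise SequenceError(f"non-ACGT character in {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(seq: str) -> str:
    """Reverse complement allowing IUPAC ambiguity codes (recognition seqs)."""
    return seq.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into an overlap-aware regex (lookahead)."""
    try:
        body = "".join(f"[{IUPAC[c]}]" for c in pattern.upper())
    except KeyError as exc:  # pragma: no cover - guarded at Enzyme construction
        raise SequenceError(f"invalid IUPAC code {exc} in {pattern!r}") from exc
    return re.compile(f"(?=({body}))")


@dataclass
class Feature:
    """Annotation on the top strand.

    ``start``/``end`` are 0-based half-open; for circular molecules
    ``start > end`` denotes an origin-spanning span.
    """

    label: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "misc_feature"
    note: str = ""

    def length(self, molecule_length: Optional[int] = None) -> int:
        if self.end >= self.start:
            return self.end - self.start
        if molecule_length is None:
            raise SequenceError("origin-spanning feature on linear molecule")
        return molecule_length - self.start + self.end


@dataclass
class DnaMolecule:
    """An annotated linear or circular double-stranded DNA molecule."""

    seq: str
    topology: str = "linear"
    features: List[Feature] = field(default_factory=list)
    name: str = "molecule"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceError(f"{self.name}: empty sequence")
        if not re.fullmatch(r"[ACGT]+", self.seq):
            bad = sorted(set(self.seq) - set("ACGT"))
            raise SequenceError(f"{self.name}: ambiguity/invalid codes {bad} rejected")
        if self.topology not in ("linear", "circular"):
            raise SequenceError(f"{self.name}: topology must be linear or circular")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def cyclic_slice(self, start: int, span: int) -> str:
        """Top-strand window of ``span`` nt starting at ``start`` (mod length)."""
        L = len(self.seq)
        start %= L
        if not self.is_circular and start + span > L:
            raise SequenceError("slice beyond end of linear molecule")
        doubled = self.seq + self.seq
        if span > L:
            raise SequenceError("slice longer than molecule")
        return doubled[start:start + span]


@dataclass(frozen=True)
class RestrictionSite:
    """A Type IIS recognition occurrence with its computed cut coordinates.

    ``cut_top`` is normalised into ``[0, L)``; ``cut_bottom = cut_top +
    overhang_len`` and may exceed the length for origin-spanning cuts on
    circular molecules.
    """

    enzyme: "Enzyme"
    strand: str
    recog_start: int
    cut_top: int
    cut_bottom: int


@dataclass
class StickyFragment:
    """A digestion product with top-strand junction identities.

    ``core`` is the physical top strand of the fragment: it *includes* the
    left-junction bases (the 5' single-stranded extension) and *excludes* the
    right-junction bases, which ride on the bottom strand.  Concatenating
    cores of consecutive fragments therefore reconstructs the source.
    """

    core: str
    left_junction: Optional[str]
    right_junction: Optional[str]
    source: str = ""
    source_start: int = 0
    source_end: int = 0
    features: List[Feature] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.source}[{self.source_start}:{self.source_end}]"

    @property
    def blunt_left(self) -> bool:
        return self.left_junction is None

    @property
    def blunt_right(self) -> bool:
        return self.right_junction is None

    def __len__(self) -> int:
        return len(self.core)


class Digestion(Sequence):
    """Result of digesting one molecule: behaves as a list of fragments.

    A circular molecule with zero sites yields ``uncut=True`` with no
    fragments -- a distinguishable non-error outcome.
    """

    def __init__(self, fragments: List[StickyFragment], uncut: bool = False,
                 molecule: Optional[DnaMolecule] = None):
        self.fragments = fragments
        self.uncut = uncut
        self.molecule = molecule

    def __len__(self) -> int:
        return len(self.fragments)

    def __getitem__(self, i):
        return self.fragments[i]

    def __iter__(self) -> Iterator[StickyFragment]:
        return iter(self.fragments)


def find_sites(m: DnaMolecule, e: "Enzyme") -> List[RestrictionSite]:
    """All recognition occurrences of ``e`` on both strands of ``m``.

    Circular molecules are scanned with wraparound so origin-spanning sites
    are found.  On linear molecules a recognition whose cut window falls off
    either end is still reported (with its computed, possibly out-of-range
    cut coordinates); ``digest`` skips such un-cuttable sites.
    """
    L = len(m.seq)
    rlen = len(e.recognition)
    window = rlen + e.spacer_len + e.overhang_len
    if m.is_circular:
        reps = (L + window - 1) // L + 1
        scan = (m.seq * reps)[: L + window - 1]
    else:
        scan = m.seq

    sites: List[RestrictionSite] = []
    for strand, pattern in (("+", e.recognition), ("-", revcomp_iupac(e.recognition))):
        rx = iupac_regex(pattern)
        for match in rx.finditer(scan):
            p = match.start()
            if p >= L:
                continue
            if strand == "+":
                cut_top = p + rlen + e.spacer_len
            else:
                cut_top = p - e.spacer_len - e.overhang_len
            cut_bottom = cut_top + e.overhang_len
            if m.is_circular:
                cut_top %= L
                cut_bottom = cut_top + e.overhang_len
            sites.append(RestrictionSite(e, strand, p, cut_top, cut_bottom))
    sites.sort(key=lambda s: (s.recog_start, s.strand))
    return sites


#: feature kinds that describe an assembly rather than sequence content;
#: they are not carried through a further digestion (the new assembly gets
#: fresh ones from the ligation step).
_BOOKKEEPING_KINDS = frozenset({"part", "junction", "fragment"})


def _clip_features(features: Iterable[Feature], start: int, span: int,
                   L: int, circular: bool) -> List[Feature]:
    """Re-coordinate features into the window ``[start, start+span)``."""
    out: List[Feature] = []
    for f in features:
        if f.kind in _BOOKKEEPING_KINDS:
            continue
        flen = f.length(L if circular else None)
        fs = (f.start - start) % L if circular else f.start - start
        # circular features mapping beyond the window may still poke in from
        # the left once wrapped; a second candidate offset covers that.
        candidates = [fs]
        if circular:
            candidates.append(fs - L)
        for cfs in candidates:
            new_start = max(cfs, 0)
            new_end = min(cfs + flen, span)
            if new_start < new_end:
                clipped = (cfs < 0) or (cfs + flen > span)
                note = f.note
                if clipped:
                    note = (note + "; " if note else "") + "truncated"
                out.append(replace(f, start=new_start, end=new_end, note=note))
                break
    return out


def digest(m: DnaMolecule, e: "Enzyme") -> Digestion:
    """Cut ``m`` at every site of ``e`` and return the sticky fragments.

    A linear molecule with ``k`` sites yields ``k+1`` fragments (terminal
    ends blunt); a circular molecule with ``k >= 1`` sites yields ``k``
    fragments.  Two sites cutting inside the same overhang window make the
    products ill-defined and raise :class:`DigestionError`.
    """
    L = len(m.seq)
    sites = find_sites(m, e)
    if not m.is_circular:  # cut windows falling off a linear end cannot cut
        sites = [s for s in sites if s.cut_top >= 0 and s.cut_bottom <= L]
    junctions = sorted({(s.cut_top, s.cut_bottom) for s in sites})

    if not junctions:
        if m.is_circular:
            return Digestion([], uncut=True, molecule=m)
        frag = StickyFragment(m.seq, None, None, m.name, 0, L,
                              _clip_features(m.features, 0, L, L, False))
        return Digestion([frag], molecule=m)

    # overlapping cut windows -> ambiguous products
    for (a1, b1), (a2, b2) in zip(junctions, junctions[1:]):
        if a2 < b1:
            raise DigestionError(
                f"{m.name}: overlapping cut windows at {a1} and {a2}")
    if m.is_circular and junctions[-1][1] > L + junctions[0][0]:
        raise DigestionError(f"{m.name}: overlapping cut windows across origin")

    oh = e.overhang_len
    frags: List[StickyFragment] = []
    if m.is_circular:
        starts = [a for a, _ in junctions]
        k = len(starts)
        for i in range(k):
            a = starts[i]
            b = starts[(i + 1) % k]
            span = (b - a) % L or L
            core = m.cyclic_slice(a, span)
            left = m.cyclic_slice(a, oh)
            right = m.cyclic_slice(b, oh)
            frags.append(StickyFragment(
                core, left, right, m.name, a, (a + span) % L,
                _clip_features(m.features, a, span, L, True)))
    else:
        bounds = [0] + [a for a, _ in junctions] + [L]
        ohs = [None] + [m.seq[a:b] for a, b in junctions] + [None]
        for i in range(len(bounds) - 1):
            a, b = bounds[i], bounds[i + 1]
            frags.append(StickyFragment(
                m.seq[a:b], ohs[i], ohs[i + 1], m.name, a, b,
                _clip_features(m.features, a, b - a, L, False)))
    return Digestion(frags, molecule=m)


def canonical_rotation(m: DnaMolecule) -> DnaMolecule:
    """Rotate a circular molecule to its lexicographically smallest top strand.

    Ties break at the smallest offset; the strand is never flipped.  Features
    are re-coordinated (origin-spanning spans use ``start > end``).
    """
    if not m.is_circular:
        raise SequenceError("canonical_rotation requires a circular molecule")
    L = len(m.seq)
    doubled = m.seq + m.seq
    best_i = 0
    for i in range(1, L):
        if doubled[i:i + L] < doubled[best_i:best_i + L]:
            best_i = i
    if best_i == 0:
        return m
    new_feats = []
    for f in m.features:
        flen = f.length(L)
        ns = (f.start - best_i) % L
        ne = ns + flen
        if ne > L:
            ne -= L
        new_feats.append(replace(f, start=ns, end=ne))
    return DnaMolecule(doubled[best_i:best_i + L], "circular", new_feats, m.name)


def rotations(seq: str) -> List[str]:
    """All rotations of ``seq`` (brute-force helper, used by tests/oracles)."""
    return [seq[i:] + seq[:i] for i in range(len(seq))]
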