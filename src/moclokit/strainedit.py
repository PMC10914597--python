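"""Sequence-level strain-engineering design: edits, split-marker cassettes,
Cre/lox excision.

These operations model genome engineering purely at the sequence level:
homologous replacement is composed from :func:`apply_edit`, the split-marker
method is index arithmetic on the marker, and Cre recombination is modelled
as direct-repeat excision leaving a single lox scar (inversion between
head-to-head lox sites is deliberately unsupported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Tuple

from .errors import EditError, ExcisionError, SplitMarkerError
from .seqcore import DnaMolecule, Feature, revcomp

#: Canonical 34-bp loxP site (13-bp inverted repeats around an 8-bp spacer).
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"


@dataclass
class Edit:
    """A single engineered change, 1-based on the top strand."""

    kind: str                     # deletion | insertion | replacement
    pos: int
    payload: str = ""             # for insertion / replacement
    length: int = 0               # for deletion / replacement

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion", "replacement"):
            raise EditError(f"unknown edit kind {self.kind!r}")
        self.payload = self.payload.upper()
        if self.payload and not set(self.payload) <= set("ACGT"):
            raise EditError("payload must be ACGT")
        if self.kind == "insertion" and not self.payload:
            raise EditError("insertion needs a payload")
        if self.kind in ("deletion", "replacement") and self.length < 1:
            raise EditError(f"{self.kind} needs length >= 1")


def _shift_features(features: List[Feature], p0: int, removed: int,
                    inserted: int) -> List[Feature]:
    """Re-coordinate features across an edit replacing ``removed`` bases at
    0-based ``p0`` with ``inserted`` bases.  Features wholly inside the
    removed span are dropped; partial overlaps are truncated and flagged."""
    delta = inserted - removed
    out: List[Feature] = []
    for f in features:
        start, end = f.start, f.end
        if end <= p0:                           # entirely upstream
            out.append(replace(f))
            continue
        if start >= p0 + removed:               # entirely downstream
            out.append(replace(f, start=start + delta, end=end + delta))
            continue
        if start >= p0 and end <= p0 + removed:  # wholly inside deletion
            continue
        note = (f.note + "; " if f.note else "") + "truncated by edit"
        new_start = start if start < p0 else p0 + inserted
        new_end = p0 if end <= p0 + removed else end + delta
        if new_start < new_end:
            out.append(replace(f, start=new_start, end=new_end, note=note))
    return out


def apply_edit(m: DnaMolecule, e: Edit) -> DnaMolecule:
    """Return the edited molecule with features re-coordinated."""
    L = len(m.seq)
    p0 = e.pos - 1
    if p0 < 0 or p0 >= L:
        raise EditError(f"position {e.pos} outside molecule of length {L}")
    if e.kind == "insertion":
        seq = m.seq[:p0] + e.payload + m.seq[p0:]
        feats = _shift_features(m.features, p0, 0, len(e.payload))
    elif e.kind == "deletion":
        if p0 + e.length > L:
            raise EditError("deletion extends beyond molecule end")
        seq = m.seq[:p0] + m.seq[p0 + e.length:]
        feats = _shift_features(m.features, p0, e.length, 0)
    else:  # replacement
        if p0 + e.length > L:
            raise EditError("replacement extends beyond molecule end")
        seq = m.seq[:p0] + e.payload + m.seq[p0 + e.length:]
        feats = _shift_features(m.features, p0, e.length, len(e.payload))
    return DnaMolecule(seq, m.topology, feats, m.name)


@dataclass
class SplitMarkerPair:
    """The two overlapping transformation fragments of a split-marker design.

    ``fragment_left`` = left homology + 5' portion of the marker;
    ``fragment_right`` = 3' portion of the marker + right homology.  Their
    marker portions overlap by ``overlap_len`` bases, so only correct
    recombination at the locus reconstitutes a functional marker.
    """

    fragment_left: str
    fragment_right: str
    overlap_len: int
    hom_left_len: int
    hom_right_len: int

    @property
    def merged(self) -> str:
        """hom_left + full marker + hom_right, reconstructed via the overlap."""
        return self.fragment_left + self.fragment_right[self.overlap_len:]


def design_split_marker(hom_left: str, hom_right: str, marker: str,
                        split_spec: Tuple[float, float] = (2 / 3, 2 / 3)
                        ) -> SplitMarkerPair:
    """Split a selectable marker into two overlapping PCR-style fragments.

    With the default split (first and last two-thirds of the marker) the
    overlap is about one third of the marker length: ``ceil(2L/3)*2 - L``.
    A non-positive overlap is a design error.
    """
    hom_left, hom_right = hom_left.upper(), hom_right.upper()
    marker = marker.upper()
    L = len(marker)
    if L < 3:
        raise SplitMarkerError("marker shorter than 3 nt")
    f1, f2 = split_spec
    left_take = math.ceil(f1 * L)
    right_take = math.ceil(f2 * L)
    overlap = left_take + right_take - L
    if overlap <= 0:
        raise SplitMarkerError(
            f"split ({f1:.3g}, {f2:.3g}) of a {L}-nt marker leaves no overlap")
    pair = SplitMarkerPair(hom_left + marker[:left_take],
                           marker[L - right_take:] + hom_right,
                           overlap, len(hom_left), len(hom_right))
    assert pair.merged == hom_left + marker + hom_right
    return pair


@dataclass
class ExcisionResult:
    """Outcome of a Cre/lox excision attempt."""

    molecule: DnaMolecule
    excised: bool
    message: str = ""


def cre_excise(m: DnaMolecule, lox: str = LOXP) -> ExcisionResult:
    """Excise the span between the first direct-repeat lox pair.

    Exactly one lox copy remains, so repeated application is a no-op.  Fewer
    than two same-orientation copies is a "nothing to excise" result (the
    molecule is returned unchanged); a head-to-head pair with no direct pair
    raises :class:`ExcisionError` because inversion is not modelled.
    """
    lox = lox.upper()
    fwd = _occurrences(m.seq, lox)
    rev = _occurrences(m.seq, revcomp(lox))
    if len(fwd) >= 2 or len(rev) >= 2:
        starts = fwd if len(fwd) >= 2 else rev
        s1, s2 = starts[0], starts[1]
        edit = Edit("deletion", pos=s1 + 1, length=s2 - s1)
        return ExcisionResult(apply_edit(m, edit), True,
                              f"excised {s2 - s1} nt between direct lox repeats")
    if fwd and rev:
        raise ExcisionError("only inverted-repeat lox pair found; inversion "
                            "is not modelled")
    return ExcisionResult(m, False, "nothing to excise (fewer than two "
                                    "direct-repeat lox sites)")


def _occurrences(seq: str, pattern: str) -> List[int]:
    out, i = [], seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def integrate_cassette(locus: DnaMolecule, target_start: int, target_len: int,
                       pair: SplitMarkerPair) -> DnaMolecule:
    """Simulate homologous replacement of ``[target_start, +target_len)``
    (1-based) by the reconstituted split-marker cassette's marker portion.

    The homology arms of ``pair`` are assumed to match the locus flanks; the
    replacement is composed from :func:`apply_edit` rather than modelling
    recombination mechanistically.
    """
    marker = pair.merged[pair.hom_left_len:
                         len(pair.merged) - pair.hom_right_len]
    edit = Edit("replacement", pos=target_start, payload=marker,
                length=target_len)
    return apply_edit(locus, edit)
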