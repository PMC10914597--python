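"""MoClo part-type grammar: slots, overhangs, enzymes, split rules.

A grammar is an ordered ring of part types.  Each part type carries the
4-nt fusion-site overhangs on its left and right; consecutive ring members
share a junction overhang and the last member wraps to the first, so a full
one-part-per-slot assembly closes into exactly one circle.  Two Type IIS
enzymes drive the level hierarchy: the *entry* enzyme opens entry (Level 0)
backbones and builds multigene (Level 2) vectors, the *cassette* enzyme
releases typed parts for Level 1 expression-vector assembly.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Union

import yaml

from .errors import ExpansionError, GrammarError
from .seqcore import IUPAC, revcomp

#: Reference cut geometries for enzymes a config may name without details.
#: spacer_len = nt between the recognition 3' end and the top-strand cut;
#: overhang_len = length of the 5' extension produced.
KNOWN_ENZYMES = {
    "BsaI": ("GGTCTC", 1, 4),
    "BsmBI": ("CGTCTC", 1, 4),
    "BbsI": ("GAAGAC", 2, 4),
    "SapI": ("GCTCTTC", 1, 3),
}


@dataclass(frozen=True)
class Enzyme:
    """A Type IIS restriction endonuclease cutting outside its site."""

    name: str
    recognition: str
    spacer_len: int
    overhang_len: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        if not self.recognition or any(c not in IUPAC for c in self.recognition):
            raise GrammarError(f"enzyme {self.name}: invalid IUPAC recognition "
                               f"{self.recognition!r}")
        if self.spacer_len < 0:
            raise GrammarError(f"enzyme {self.name}: spacer_len must be >= 0 "
                               "(Type IIS enzymes cut outside their site)")
        if self.overhang_len < 1:
            raise GrammarError(f"enzyme {self.name}: overhang_len must be >= 1; "
                               "blunt or 3'-overhang cutters are not supported")


def check_overhang(seq: str, length: int = 4, *, where: str = "overhang") -> str:
    """Validate and canonicalize a fusion-site overhang (uppercase ACGT)."""
    s = str(seq).upper()
    if len(s) != length or not re.fullmatch(r"[ACGT]+", s):
        raise GrammarError(f"{where}: malformed overhang {seq!r} "
                           f"(need {length} nt over ACGT)")
    return s


@dataclass
class PartType:
    """One slot of the assembly ring, bounded by its fusion-site overhangs."""

    slot_id: str
    role: str
    left: str
    right: str
    splittable_children: List[str] = field(default_factory=list)


@dataclass
class Violation:
    """One broken grammar invariant, as reported by validate_grammar."""

    kind: str
    message: str
    slots: List[str] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.message}"


@dataclass
class Grammar:
    """An ordered ring of part types plus the two assembly enzymes."""

    part_types: List[PartType]
    enzyme_entry: Enzyme
    enzyme_cassette: Enzyme
    entry_left: str
    entry_right: str
    split_types: Dict[str, PartType] = field(default_factory=dict)
    name: str = "grammar"
    source_text: str = ""

    @property
    def slot_ids(self) -> List[str]:
        return [p.slot_id for p in self.part_types]

    @property
    def backbone_slot(self) -> PartType:
        """The ring member that carries the vector body and closes the ring."""
        for p in self.part_types:
            if "backbone" in p.role or "origin" in p.role:
                return p
        return self.part_types[-1]

    def slot(self, slot_id: str) -> PartType:
        for p in self.part_types:
            if p.slot_id == str(slot_id):
                return p
        st = self.split_types.get(str(slot_id))
        if st is not None:
            return st
        raise GrammarError(f"unknown slot {slot_id!r} in grammar {self.name}")

    def ring_overhangs(self) -> List[str]:
        """Junction overhangs around the top-level ring, one per junction."""
        return [p.left for p in self.part_types]

    def all_overhangs(self) -> List[str]:
        """Ring plus split-junction plus entry overhangs (deduplicated)."""
        seen: List[str] = []
        for o in (self.ring_overhangs()
                  + [p.left for p in self.split_types.values()]
                  + [p.right for p in self.split_types.values()]
                  + [self.entry_left, self.entry_right]):
            if o not in seen:
                seen.append(o)
        return seen

    def config_hash(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:12]


def _build_enzyme(name: str, spec: Optional[dict], role: str) -> Enzyme:
    if spec is None:
        spec = {}
    ename = spec.get("name", name)
    if "recognition" in spec:
        return Enzyme(ename, spec["recognition"],
                      int(spec.get("spacer_len", 1)),
                      int(spec.get("overhang_len", 4)))
    if ename in KNOWN_ENZYMES:
        recog, spacer, oh = KNOWN_ENZYMES[ename]
        return Enzyme(ename, recog, spacer, oh)
    raise GrammarError(f"enzymes.{role}: unknown enzyme {ename!r} and no "
                       "recognition/spacer geometry given")


def load_grammar(source: Union[str, dict], name: str = "grammar") -> Grammar:
    """Load a grammar from YAML text, a file path, or a parsed mapping.

    Unspecified enzyme geometry falls back to the shipped reference values in
    :data:`KNOWN_ENZYMES`.  Structural errors (missing slot, malformed
    overhang, unknown enzyme) raise :class:`GrammarError` naming the key.
    """
    text = ""
    if isinstance(source, dict):
        cfg = source
        text = yaml.safe_dump(source)
    else:
        s = str(source)
        if "\n" not in s and (s.endswith(".yaml") or s.endswith(".yml")):
            with open(s) as fh:
                text = fh.read()
        else:
            text = s
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise GrammarError("grammar config must be a mapping")

    enz_cfg = cfg.get("enzymes") or {}
    if "entry" not in enz_cfg or "cassette" not in enz_cfg:
        raise GrammarError("enzymes: both 'entry' and 'cassette' must be declared")
    e_entry = _build_enzyme("entry", enz_cfg["entry"], "entry")
    e_cassette = _build_enzyme("cassette", enz_cfg["cassette"], "cassette")
    oh_len = e_cassette.overhang_len

    slots_cfg = cfg.get("slots")
    if not slots_cfg:
        raise GrammarError("slots: at least one slot must be declared")
    part_types: List[PartType] = []
    for i, sc in enumerate(slots_cfg):
        for key in ("id", "left", "right"):
            if key not in sc:
                raise GrammarError(f"slots[{i}]: missing key {key!r}")
        sid = str(sc["id"])
        part_types.append(PartType(
            sid, str(sc.get("role", "")),
            check_overhang(sc["left"], oh_len, where=f"slots[{sid}].left"),
            check_overhang(sc["right"], oh_len, where=f"slots[{sid}].right")))

    splits = {str(k): [str(c) for c in v] for k, v in (cfg.get("splits") or {}).items()}
    split_types: Dict[str, PartType] = {}
    for i, sc in enumerate(cfg.get("split_slots") or []):
        sid = str(sc["id"])
        split_types[sid] = PartType(
            sid, str(sc.get("role", "")),
            check_overhang(sc["left"], oh_len, where=f"split_slots[{sid}].left"),
            check_overhang(sc["right"], oh_len, where=f"split_slots[{sid}].right"))
    for parent, children in splits.items():
        pt = next((p for p in part_types if p.slot_id == parent), None)
        if pt is None:
            raise GrammarError(f"splits: unknown parent slot {parent!r}")
        missing = [c for c in children if c not in split_types]
        if missing:
            raise GrammarError(f"splits.{parent}: undeclared children {missing}")
        pt.splittable_children = children

    entry = cfg.get("entry_overhangs") or {}
    e_oh = e_entry.overhang_len
    entry_left = check_overhang(entry.get("left", "A" * e_oh), e_oh,
                                where="entry_overhangs.left")
    entry_right = check_overhang(entry.get("right", "T" * e_oh), e_oh,
                                 where="entry_overhangs.right")

    return Grammar(part_types, e_entry, e_cassette, entry_left, entry_right,
                   split_types, name=str(cfg.get("name", name)), source_text=text)


def _shipped(filename: str) -> str:
    return resources.files("moclokit.data").joinpath(filename).read_text()


def default_grammar() -> Grammar:
    """The shipped eight-slot grammar (yeast-toolkit overhang convention)."""
    return load_grammar(_shipped("default_grammar.yaml"), name="default")


def toy_grammar() -> Grammar:
    """The shipped miniature-kit grammar with its own synthetic overhang set."""
    return load_grammar(_shipped("toy_grammar.yaml"), name="toy")


def get_grammar(spec: str) -> Grammar:
    """Resolve ``'default'``, ``'toy'`` or a config path to a Grammar."""
    if spec == "default":
        return default_grammar()
    if spec == "toy":
        return toy_grammar()
    return load_grammar(spec)


def validate_grammar(g: Grammar) -> List[Violation]:
    """Check every grammar invariant; returns one record per violation.

    Validation never throws: an empty list means the grammar is sound.
    Checked: ring closure (right of slot k = left of slot k+1, wrapping),
    pairwise-distinct junction overhangs, no palindromic (self-complementary)
    overhang, and split rules that partition their parent.
    """
    out: List[Violation] = []
    ring = g.part_types
    n = len(ring)
    for i, p in enumerate(ring):
        q = ring[(i + 1) % n]
        if p.right != q.left:
            out.append(Violation(
                "broken ring",
                f"slot {p.slot_id} right ({p.right}) != slot {q.slot_id} "
                f"left ({q.left})", [p.slot_id, q.slot_id]))
    junctions = g.ring_overhangs()
    seen: Dict[str, str] = {}
    for p in ring:
        if p.left in seen:
            out.append(Violation(
                "duplicate overhang",
                f"overhang {p.left} used at junctions of slots "
                f"{seen[p.left]} and {p.slot_id}", [seen[p.left], p.slot_id]))
        else:
            seen[p.left] = p.slot_id
    for o in dict.fromkeys(g.all_overhangs()):
        try:
            if revcomp(o) == o:
                out.append(Violation(
                    "palindromic overhang",
                    f"overhang {o} equals its own reverse complement "
                    "(self-ligating end)"))
        except Exception:  # pragma: no cover - overhangs validated at load
            pass
    for p in ring:
        if not p.splittable_children:
            continue
        children = [g.split_types[c] for c in p.splittable_children
                    if c in g.split_types]
        if len(children) != len(p.splittable_children):
            out.append(Violation("split rule",
                                 f"slot {p.slot_id}: undeclared split children",
                                 [p.slot_id]))
            continue
        if children[0].left != p.left or children[-1].right != p.right:
            out.append(Violation(
                "split rule",
                f"slot {p.slot_id}: children do not span parent overhangs",
                [p.slot_id]))
        for a, b in zip(children, children[1:]):
            if a.right != b.left:
                out.append(Violation(
                    "split rule",
                    f"slot {p.slot_id}: children {a.slot_id}/{b.slot_id} do "
                    "not share a junction", [a.slot_id, b.slot_id]))
            if a.right in junctions:
                out.append(Violation(
                    "duplicate overhang",
                    f"split junction {a.right} collides with a ring junction",
                    [a.slot_id, b.slot_id]))
    return out


def expand_slots(g: Grammar, requested: Sequence[str]) -> List[PartType]:
    """Expand a slot request into the fully ordered ring of part types.

    ``requested`` must name each top-level slot exactly once, optionally
    replacing a splittable parent by its full set of children.  The result is
    in ring order and satisfies the same ring-closure predicate as the
    parent grammar.
    """
    req = [str(s) for s in requested]
    if len(req) != len(set(req)):
        dupes = sorted({s for s in req if req.count(s) > 1})
        raise ExpansionError(f"duplicate slot(s) {dupes} in request")
    child_to_parent = {c: p.slot_id for p in g.part_types
                       for c in p.splittable_children}
    unknown = [s for s in req if s not in g.slot_ids and s not in child_to_parent]
    if unknown:
        raise ExpansionError(f"unknown slot(s) {unknown}")

    remaining = set(req)
    expanded: List[PartType] = []
    for p in g.part_types:
        kids = p.splittable_children
        if p.slot_id in remaining and any(k in remaining for k in kids):
            conflict = next(k for k in kids if k in remaining)
            raise ExpansionError(
                f"slot {p.slot_id} and child {conflict} both present")
        if p.slot_id in remaining:
            expanded.append(p)
            remaining.discard(p.slot_id)
        elif kids and all(k in remaining for k in kids):
            expanded.extend(g.split_types[k] for k in kids)
            remaining.difference_update(kids)
        elif any(k in remaining for k in kids):
            present = [k for k in kids if k in remaining]
            raise ExpansionError(
                f"slot {p.slot_id}: incomplete split {present} (need all of {kids})")
        else:
            raise ExpansionError(f"missing slot {p.slot_id}")
    if remaining:  # pragma: no cover - defensive; caught above as duplicates
        raise ExpansionError(f"unplaceable slot(s) {sorted(remaining)}")
    return expanded
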