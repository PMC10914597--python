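"""Part-library loading, part-type classification and annotated export.

FASTA headers use the dialect ``>{id} [type=<slot>] [topology=circular]
[free text]``; plain headers are accepted and classification then relies on
:func:`classify_part`.  GenBank files carry the circular-topology flag and
round-trip features; coordinates are converted between the internal 0-based
half-open model and GenBank's 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .assembly import AssemblyProduct
from .errors import PartLibraryError, SequenceError
from .grammar import Grammar
from .seqcore import DnaMolecule, Feature, digest


# ---------------------------------------------------------------------------
# FASTA

def _header_tokens(description: str) -> dict:
    return dict(t.split("=", 1) for t in description.split()[1:] if "=" in t)


def read_fasta(path) -> List[DnaMolecule]:
    """Read molecules from FASTA; ``topology=circular`` tokens are honoured."""
    mols = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = _header_tokens(rec.description)
        topology = tokens.get("topology", "linear")
        mols.append(DnaMolecule(str(rec.seq).upper(), topology, [], rec.id))
    if not mols:
        raise PartLibraryError(f"{path}: no FASTA records")
    return mols


def write_fasta(molecules: Sequence[DnaMolecule], path,
                extra_tokens: Optional[dict] = None) -> None:
    """Write molecules as 60-column wrapped FASTA with topology tokens."""
    with open(path, "w") as fh:
        for m in molecules:
            tokens = {"topology": m.topology}
            if extra_tokens and m.name in extra_tokens:
                tokens.update(extra_tokens[m.name])
            tok = " ".join(f"{k}={v}" for k, v in tokens.items())
            fh.write(f">{m.name} {tok}\n")
            for i in range(0, len(m.seq), 60):
                fh.write(m.seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# GenBank

def molecule_to_seqrecord(m: DnaMolecule) -> SeqRecord:
    rec = SeqRecord(Seq(m.seq), id=m.name[:16] or "molecule", name=m.name[:16],
                    description=m.name)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = m.topology
    L = len(m.seq)
    for f in m.features:
        if m.is_circular and f.end < f.start:      # origin-spanning
            loc = FeatureLocation(f.start, L) + FeatureLocation(0, f.end)
        else:
            loc = FeatureLocation(f.start, f.end)
        sf = SeqFeature(loc, type=f.kind[:15] or "misc_feature",
                        qualifiers={"label": [f.label]})
        if f.note:
            sf.qualifiers["note"] = [f.note]
        sf.qualifiers["strand_sign"] = [f.strand]
        rec.features.append(sf)
    return rec


def seqrecord_to_molecule(rec: SeqRecord) -> DnaMolecule:
    topology = rec.annotations.get("topology", "linear")
    feats = []
    for sf in rec.features:
        label = (sf.qualifiers.get("label") or [sf.type])[0]
        note = (sf.qualifiers.get("note") or [""])[0]
        strand = (sf.qualifiers.get("strand_sign") or
                  ["+" if (sf.location.strand or 1) >= 0 else "-"])[0]
        parts = getattr(sf.location, "parts", [sf.location])
        start = int(parts[0].start)
        end = int(parts[-1].end)
        if len(parts) > 1 and topology == "circular":
            end = int(parts[-1].end)  # origin-spanning: start > end
        feats.append(Feature(label, start, end, strand, sf.type, note))
    return DnaMolecule(str(rec.seq).upper(), topology, feats,
                       rec.description or rec.id)


def write_genbank(m: DnaMolecule, path) -> None:
    SeqIO.write([molecule_to_seqrecord(m)], str(path), "genbank")


def read_genbank(path) -> DnaMolecule:
    rec = SeqIO.read(str(path), "genbank")
    return seqrecord_to_molecule(rec)


# ---------------------------------------------------------------------------
# Part libraries

@dataclass
class PartRecord:
    """One entry of a part library with its declared and inferred slot."""

    id: str
    declared_slot: Optional[str]
    molecule: DnaMolecule
    classified_slot: Optional[str] = None
    notes: str = ""


def read_part_library(path, g: Optional[Grammar] = None) -> List[PartRecord]:
    """Load a part-library FASTA; classify each entry when a grammar is given.

    Headers may carry ``type=<slot>`` tokens; duplicate ids and empty files
    raise :class:`PartLibraryError`.
    """
    records: List[PartRecord] = []
    seen = set()
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise PartLibraryError(f"{path}: empty part library")
    for rec in parsed:
        if rec.id in seen:
            raise PartLibraryError(f"{path}: duplicate part id {rec.id!r}")
        seen.add(rec.id)
        tokens = _header_tokens(rec.description)
        mol = DnaMolecule(str(rec.seq).upper(),
                          tokens.get("topology", "linear"), [], rec.id)
        pr = PartRecord(rec.id, tokens.get("type"), mol)
        if g is not None:
            pr.classified_slot = classify_part(mol, g)
            if pr.classified_slot is None:
                pr.notes = "unclassifiable: no unique slot junction match"
        records.append(pr)
    return records


def classify_part(m: DnaMolecule, g: Grammar) -> Optional[str]:
    """Infer the grammar slot of a Level 0 plasmid or typed fragment.

    The molecule is digested with the cassette enzyme; the fragment whose
    (left, right) junction pair matches exactly one slot (top-level or split)
    determines the slot.  No sites, no match or an ambiguous match returns
    ``None`` (unclassifiable).
    """
    try:
        d = digest(m, g.enzyme_cassette)
    except SequenceError:
        return None
    if d.uncut or not d.fragments:
        return None
    candidates = list(g.part_types) + list(g.split_types.values())
    hits = []
    for f in d.fragments:
        if f.left_junction is None or f.right_junction is None:
            continue
        matches = [p.slot_id for p in candidates
                   if p.left == f.left_junction and p.right == f.right_junction]
        if len(matches) == 1:
            hits.append(matches[0])
    hits = sorted(set(hits))
    return hits[0] if len(hits) == 1 else None


def write_product_genbank(p: AssemblyProduct, path) -> None:
    """Export a stable assembly as circular GenBank with part and junction
    features; refuses unstable products."""
    if p.stable is False:
        raise PartLibraryError("refusing to export an unstable product "
                               "(residual active-enzyme sites)")
    write_genbank(p.molecule, path)


def junction_report(p: AssemblyProduct) -> str:
    """Tabular text report: slot/fragment, overhang, length per junction."""
    lines = ["fragment\toverhang\tlength_bp"]
    for j, f in zip(p.junctions, p.fragments):
        lines.append(f"{f.name}\t{f.right_junction}\t{len(f.core)}")
    return "\n".join(lines) + "\n"
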