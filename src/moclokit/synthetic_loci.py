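"""Synthetic worked-example loci for the frameshift/stop-distance analyses.

These are *synthetic* surrogate sequences, constructed to carry the exact
arithmetic of the documented alpha-1,6-mannosyltransferase (HOC1) truncation
allele of *Komagataella phaffii*: a 1,191-bp coding sequence with a poly-A
stretch around position 749-756 such that deleting one base at CDS position
755 shifts the frame in codon 252 and the shifted frame runs through 22
further sense codons before its first stop, giving a 274-aa truncated
protein.  They are NOT the genomic HOC1 sequence; reconstructing the real
locus requires the published reference assembly.  Note the full-length
surrogate translates to 396 aa -- the value consistent with a 1,191-bp CDS
(1191/3 - 1); the commonly quoted 398-aa figure cannot be reconciled with
that CDS length.

A second builder produces a truncated-allele locus with a configurable
premature-to-canonical stop separation (default 405 nt), used to model the
effect of deleting a further block (e.g. 115 bp) downstream of the premature
stop.
"""

from __future__ import annotations

from .codon import translate
from .seqcore import DnaMolecule, Feature

#: sense codons cycled to fill structurally unconstrained regions
_FILLER = ["GCT", "GAA", "CTG", "TCT", "GAC", "AAG", "ATC", "CCA", "GTT", "AAC"]


def _fill(n_codons: int) -> str:
    return "".join(_FILLER[i % len(_FILLER)] for i in range(n_codons))


def synthetic_hoc1_cds() -> str:
    """Synthetic 1,191-bp surrogate of the full-length HOC1-like CDS.

    Layout (1-based codons of the 397-codon frame, stop included):
      1        ATG
      2-248    filler sense codons
      249-252  AAA x4      (poly-A stretch, nt 745-756)
      253-274  GCA x22     (sense in both the original and the -1 frame)
      275      CTA
      276      AAA         (the -1 frame reads ...TAA across codons 275/276)
      277-396  filler sense codons
      397      TAA         (canonical stop, nt 1189-1191)

    Deleting nt 755 therefore yields a 274-aa product with a premature stop,
    the frameshift sitting in codon 252 and 22 altered codons after it.
    """
    cds = ("ATG" + _fill(247) + "AAA" * 4 + "GCA" * 22 + "CTA" + "AAA"
           + _fill(120) + "TAA")
    assert len(cds) == 1191
    t = translate(cds)
    assert t.stopped and len(t.protein) == 396
    return cds


def synthetic_hoc1_molecule() -> DnaMolecule:
    """The surrogate CDS as an annotated molecule."""
    cds = synthetic_hoc1_cds()
    feats = [Feature("CDS", 0, len(cds), "+", "CDS"),
             Feature("poly-A stretch", 744, 756, "+", "misc_feature"),
             Feature("canonical stop", 1188, 1191, "+", "misc_feature")]
    return DnaMolecule(cds, "linear", feats, "synthetic_hoc1_cds")


def synthetic_truncated_locus(stop_separation: int = 405) -> DnaMolecule:
    """Synthetic truncated-allele CDS with a premature stop separated from
    the canonical stop by ``stop_separation`` nt (default 405, the documented
    separation in the engineered truncation allele).

    The region between the stops is stop-free filler; the canonical stop is
    annotated as a feature so that downstream deletions (e.g. removing 115 bp
    after the premature stop) can be tracked through feature re-coordination.
    ``stop_separation`` must be a multiple of 3 so both stops sit in one
    frame.
    """
    if stop_separation % 3 != 0 or stop_separation < 0:
        raise ValueError("stop_separation must be a non-negative multiple of 3")
    orf_codons = 100                      # 100-aa product before the stop
    prefix = "ATG" + _fill(orf_codons - 1)
    between = _fill(stop_separation // 3)
    seq = prefix + "TAA" + between + "TAA"
    premature_start = len(prefix)          # 0-based
    canonical_start = len(prefix) + 3 + stop_separation
    feats = [Feature("premature stop", premature_start, premature_start + 3,
                     "+", "misc_feature"),
             Feature("canonical stop", canonical_start, canonical_start + 3,
                     "+", "misc_feature")]
    return DnaMolecule(seq, "linear", feats, "synthetic_truncated_locus")


def canonical_stop_pos(m: DnaMolecule) -> int:
    """1-based first base of the annotated canonical stop of a locus model."""
    for f in m.features:
        if f.label == "canonical stop":
            return f.start + 1
    raise ValueError("no 'canonical stop' feature on molecule")
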