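"""Ligation-fidelity scoring of overhang sets from pairwise frequency data.

The fidelity of a junction overhang ``o`` against a reaction pool is the
normalised Watson-Crick fraction

    fidelity(o) = t[o, wc(o)] / sum_p t[o, wc(p)]    over all p in the pool,

where ``t`` is an empirically profiled ligation-frequency table keyed by
(overhang, partner-overhang-as-top-strand-4-mer) and ``wc`` is the
Watson-Crick partner (reverse complement).  Per-junction fidelities combine
multiplicatively into the overall assembly fidelity.  The shipped default
table is WC-only and uniform (idealised: no cross-talk), under which any
valid overhang set scores exactly 1.0; load an empirical table for realistic
estimates.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple, Union

from .errors import FidelityError, LigationTableError
from .grammar import Grammar
from .seqcore import revcomp

_WORD = re.compile(r"[ACGT]+")


@dataclass
class LigationTable:
    """Pairwise overhang ligation frequencies.

    ``freq[(overhang, partner)]`` is a non-negative relative frequency; the
    partner key is recorded as the top-strand 4-mer of the partnering end.
    Missing entries are treated as zero.
    """

    freq: Dict[Tuple[str, str], float] = field(default_factory=dict)
    overhang_len: int = 4
    warnings: List[str] = field(default_factory=list)

    def get(self, overhang: str, partner: str) -> float:
        return self.freq.get((overhang, partner), 0.0)

    @classmethod
    def wc_only(cls, overhangs: Iterable[str] = (), length: int = 4,
                value: float = 1.0) -> "LigationTable":
        """Idealised table: every overhang ligates only its WC partner.

        With no explicit ``overhangs`` the table covers all 4**length
        possible overhangs.
        """
        ohs = list(overhangs)
        if not ohs:
            from itertools import product
            ohs = ["".join(p) for p in product("ACGT", repeat=length)]
        freq = {(o, revcomp(o)): value for o in ohs}
        return cls(freq, length)


def load_ligation_table(source: Union[str, io.TextIOBase]) -> LigationTable:
    """Load a (overhang, partner, frequency) table from comma/tab text.

    Rows starting with ``#`` and a header row are skipped.  Malformed 4-mers
    or negative frequencies raise :class:`LigationTableError`; overhangs
    without a Watson-Crick diagonal entry are listed in ``warnings``.
    """
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    freq: Dict[Tuple[str, str], float] = {}
    length = None
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        row = [c.strip() for c in re.split(r"[,\t ]+", line) if c.strip()]
        if len(row) != 3:
            raise LigationTableError(f"line {lineno}: need 3 columns, got {row}")
        o, p, f = row
        if not (_WORD.fullmatch(o.upper()) and _WORD.fullmatch(p.upper())):
            if length is None and not freq:
                continue  # header row
            raise LigationTableError(f"line {lineno}: malformed overhang {o!r}/{p!r}")
        o, p = o.upper(), p.upper()
        if length is None:
            length = len(o)
        if len(o) != length or len(p) != length:
            raise LigationTableError(f"line {lineno}: inconsistent overhang length")
        try:
            val = float(f)
        except ValueError:
            raise LigationTableError(f"line {lineno}: bad frequency {f!r}")
        if val < 0:
            raise LigationTableError(f"line {lineno}: negative frequency {val}")
        freq[(o, p)] = val
    if not freq:
        raise LigationTableError("empty ligation table")
    table = LigationTable(freq, length or 4)
    for o in sorted({k[0] for k in freq}):
        if (o, revcomp(o)) not in freq:
            table.warnings.append(f"overhang {o} has no Watson-Crick diagonal entry")
    return table


def junction_fidelity(o: str, pool: Iterable[str], t: LigationTable) -> float:
    """Fraction of ligations of ``o`` that go to its Watson-Crick partner.

    The denominator sums the frequency of ``o`` joining each pool member's
    annealing strand (including its own, and including a palindromic
    self-ligation term when ``o`` is its own reverse complement).  Missing
    table entries count as zero; a zero denominator raises
    :class:`FidelityError`.  Enlarging the pool can never increase fidelity.
    """
    pool = list(dict.fromkeys(pool))
    if o not in pool:
        raise FidelityError(f"overhang {o} not in pool")
    num = t.get(o, revcomp(o))
    den = sum(t.get(o, revcomp(p)) for p in pool)
    if den == 0:
        raise FidelityError(f"overhang {o}: zero total ligation frequency "
                            "(fidelity undefined)")
    return num / den


@dataclass
class FidelityReport:
    """Per-junction fidelities and their product."""

    per_junction: Dict[str, float]
    overall: float
    flagged: List[str] = field(default_factory=list)
    threshold: float = 0.95


def set_fidelity(source, t: LigationTable, *,
                 threshold: float = 0.95) -> FidelityReport:
    """Score every junction of a grammar or assembly product.

    ``source`` may be a :class:`~moclokit.grammar.Grammar` (pool = all ring,
    split and entry overhangs), an assembly product (pool = its junction
    overhangs) or a plain iterable of overhangs.  ``overall`` is the exact
    product of the per-junction values; junctions below ``threshold`` are
    flagged.
    """
    if isinstance(source, Grammar):
        pool = source.all_overhangs()
    elif hasattr(source, "junctions"):
        pool = list(dict.fromkeys(j.overhang for j in source.junctions))
    else:
        pool = list(dict.fromkeys(source))
    if not pool:
        raise FidelityError("no junction overhangs to score")
    per = {o: junction_fidelity(o, pool, t) for o in pool}
    overall = 1.0
    for v in per.values():
        overall *= v
    flagged = [o for o, v in per.items() if v < threshold]
    return FidelityReport(per, overall, flagged, threshold)
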