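"""Exception hierarchy.

Every error raised by the toolkit derives from :class:`MoCloError` so callers
(and the CLI) can catch the whole family at once.
"""


class MoCloError(Exception):
    """Base class for all toolkit errors."""


class SequenceError(MoCloError):
    """Invalid nucleotide sequence or coordinate."""


class GrammarError(MoCloError):
    """Malformed or unloadable part-type grammar configuration."""


class ExpansionError(MoCloError):
    """Invalid slot request passed to expand_slots."""


class DigestionError(MoCloError):
    """Ambiguous digestion (overlapping cut windows) or misuse of digest."""


class AssemblyError(MoCloError):
    """Golden Gate assembly did not yield the required single stable product."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class GrammarMismatchError(AssemblyError):
    """A part's junctions do not map onto the grammar slot it was given."""


class TranslationError(MoCloError):
    """CDS cannot be translated (empty, bad characters, short)."""


class DomesticationError(MoCloError):
    """A forbidden recognition site cannot be removed synonymously."""

    def __init__(self, message, stuck_sites=()):
        super().__init__(message)
        self.stuck_sites = list(stuck_sites)


class FlankDesignError(MoCloError):
    """Synthesis-flank design failed (undomesticated core, stray sites...)."""


class FrameshiftError(MoCloError):
    """Invalid edit specification or missing stop codon."""


class EditError(MoCloError):
    """Out-of-bounds or malformed sequence edit."""


class SplitMarkerError(MoCloError):
    """Split-marker design without a positive overlap."""


class ExcisionError(MoCloError):
    """Unsupported recombination configuration (e.g. inverted lox repeats)."""


class LigationTableError(MoCloError):
    """Malformed ligation-frequency table."""


class FidelityError(MoCloError):
    """Undefined fidelity (zero denominator)."""


class PartLibraryError(MoCloError):
    """Unreadable or inconsistent part library file."""
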