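"""Exception hierarchy.

All pipeline-specific failures derive from :class:`TranslatomeError` so the
CLI can map data errors to exit code 1 while argument errors stay on click's
exit code 2.
"""


class TranslatomeError(Exception):
    """Base class for all data/analysis errors raised by this package."""


class FormatError(TranslatomeError):
    """An on-disk file violates the expected format or invariants."""


class SpecError(TranslatomeError):
    """A simulation specification is internally inconsistent."""


class DesignError(TranslatomeError):
    """A statistical design is invalid (e.g. group with <2 samples)."""


class NormalizationError(TranslatomeError):
    """Size-factor normalization cannot proceed."""


class AlignmentError(TranslatomeError):
    """Two result sets that must share a feature namespace do not."""


class EnrichmentError(TranslatomeError):
    """Enrichment analysis cannot proceed (e.g. empty background)."""


class MappingError(TranslatomeError):
    """An ortholog / identifier mapping is malformed."""
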