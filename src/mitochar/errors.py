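"""Exception hierarchy for mitochar.

All package-specific failures derive from :class:`MitocharError` so callers
(and the CLI) can catch one type at the boundary.
"""


class MitocharError(Exception):
    """Base class for all mitochar errors."""


class GenomeParseError(MitocharError):
    """A genome file could not be parsed (missing sequence, bad record)."""


class FeatureError(MitocharError):
    """A gene feature is malformed or inconsistent with its genome."""


class CompositionError(MitocharError):
    """Composition statistics are undefined for the given input."""


class TranslationError(MitocharError):
    """A coding sequence violates the genetic-code contract."""


class AlignmentError(MitocharError):
    """Sequences cannot be compared position-wise (length mismatch)."""


class GenerationError(MitocharError):
    """The synthetic-genome generator could not satisfy its constraints."""
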