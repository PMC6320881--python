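"""Exception hierarchy shared across the library."""


class GlycanError(Exception):
    """Base class for all glycoforge errors."""


class VocabularyError(GlycanError):
    """A token is not a member of its controlled vocabulary."""


class StructureError(GlycanError):
    """An operation would violate a structural invariant (ranges, tree shape)."""


class AttachmentConflict(StructureError):
    """The requested attachment position is already occupied."""


class GlycoCTParseError(GlycanError):
    """Malformed GlycoCT condensed input.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedFeatureError(GlycoCTParseError):
    """Input uses a GlycoCT section this dialect deliberately rejects (UND)."""


class UnderdeterminedStructureError(GlycanError):
    """Chemical export requested for a structure that is not fully defined."""


class CatalogError(GlycanError):
    """Unknown template name."""
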