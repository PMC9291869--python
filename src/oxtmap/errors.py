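"""Exception hierarchy for oxtmap."""


class OxtmapError(Exception):
    """Base class for all package errors."""


class LoadError(OxtmapError):
    """An input file could not be read or failed validation."""


class ValidationError(OxtmapError):
    """In-memory data violated a documented invariant."""


class AnalysisError(OxtmapError):
    """A statistical operation received degenerate input."""
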