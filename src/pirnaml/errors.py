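"""Exception hierarchy shared across the package.

``DataError`` covers everything a malformed input can trigger; the CLI maps
it to exit code 3 so shell pipelines can distinguish bad data from bad usage.
"""


class PirnamlError(Exception):
    """Base class for all package errors."""


class DataError(PirnamlError):
    """Invalid or inconsistent input data."""


class AlphabetError(DataError):
    """A sequence contains a character outside {A, C, G, U} after normalization.

    ``position`` is 1-based, following sequence-coordinate convention.
    """

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        prefix = f"{context}: " if context else ""
        super().__init__(
            f"{prefix}invalid character {char!r} at position {position} "
            "(allowed after normalization: A, C, G, U)"
        )


class DuplicateIdError(DataError):
    """Duplicate record identifiers within one dataset."""

    def __init__(self, duplicates):
        self.duplicates = sorted(set(duplicates))
        super().__init__(f"duplicate sequence ids: {', '.join(self.duplicates)}")


class SchemaMismatchError(DataError):
    """Feature columns do not align with the descriptors a model expects."""

    def __init__(self, missing=(), extra=()):
        self.missing = list(missing)
        self.extra = list(extra)
        parts = []
        if self.missing:
            parts.append(f"missing descriptors: {', '.join(self.missing[:10])}")
        if self.extra:
            parts.append(f"unexpected descriptors: {', '.join(self.extra[:10])}")
        super().__init__("; ".join(parts) or "descriptor sets do not align")
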