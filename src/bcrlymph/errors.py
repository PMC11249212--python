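"""Exception hierarchy shared across the package."""


class BcrLymphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BcrLymphError, ValueError):
    """An input violates a documented precondition or invariant."""


class SchemaError(BcrLymphError, ValueError):
    """A table is missing required columns or has an unusable layout."""


class EmptyInputError(BcrLymphError, ValueError):
    """A file or record collection that must be non-empty is empty."""


class EmptyRepertoireError(BcrLymphError, ValueError):
    """No clonotypes survive filtering; a repertoire needs at least one."""
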