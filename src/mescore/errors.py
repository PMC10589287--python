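"""Exception types raised across the pipeline."""


class SchemaError(ValueError):
    """A required column is missing or a value violates its declared type."""


class IntegrityError(ValueError):
    """A table violates a uniqueness or consistency invariant."""


class ReferentialError(KeyError):
    """An identifier in one table is not resolvable in another."""


class GenerationError(RuntimeError):
    """A synthetic-data specification cannot be realized."""
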