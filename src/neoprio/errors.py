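"""Exception types shared across the package."""


class NeoprioError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(NeoprioError):
    """A tabular input violates its documented schema (missing/duplicate columns, bad cells)."""


class IntegrityError(NeoprioError):
    """Cross-references inside a metrics bundle do not resolve."""


class ConsistencyError(NeoprioError):
    """A variant description contradicts the transcript sequence it is applied to."""


class SpecError(NeoprioError):
    """A user-supplied specification string (problematic-position tokens, config) is malformed."""
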