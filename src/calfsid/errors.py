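"""Exception types shared across the package."""

from __future__ import annotations


class CalfsidError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CalfsidError):
    """An input value violates its declared bounds.

    Carries the offending field name so callers (and the CLI) can point at
    the exact column/field rather than the whole record.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class MissingAnalyteError(CalfsidError):
    """Required analytes are absent from a record or panel."""

    def __init__(self, missing: list[str]):
        self.missing = sorted(missing)
        super().__init__("missing required analytes: " + ", ".join(self.missing))


class ModelSpecificationError(CalfsidError):
    """A model file or term definition is incomplete or inconsistent."""


class SeparationError(CalfsidError):
    """Perfect separation detected while fitting a logistic model."""

    def __init__(self, term: str, coefficient: float):
        self.term = term
        self.coefficient = coefficient
        super().__init__(
            f"perfect separation suspected: coefficient for {term!r} diverged "
            f"to {coefficient:.2f} on the log-odds scale"
        )
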