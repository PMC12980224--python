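"""Exception types shared across the package."""

from __future__ import annotations


class DomainError(ValueError):
    """An input is outside the physical/mathematical domain of an operation."""


class TableValidationError(ValueError):
    """A tabular input failed schema or invariant validation.

    Carries the offending rows (1-based line numbers in the source file,
    header included) so callers can report them.
    """

    def __init__(self, message: str, rows: list[tuple[int, str]] | None = None):
        self.rows = rows or []
        if self.rows:
            detail = "; ".join(f"line {ln}: {why}" for ln, why in self.rows)
            message = f"{message} ({detail})"
        super().__init__(message)


class CollinearityError(RuntimeError):
    """A regression design matrix is rank deficient.

    ``terms`` names the columns that cannot be separated from the rest of
    the design (e.g. a squared term of a composition-invariant parameter).
    """

    def __init__(self, terms: list[str]):
        self.terms = list(terms)
        super().__init__(
            "rank-deficient design; collinear terms: " + ", ".join(self.terms)
        )


class FixtureLookupError(KeyError):
    """Requested bundled reference table does not exist."""
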