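"""Exception hierarchy for lexemo.

Every error raised by the library derives from :class:`LexemoError` so the
CLI can map failure classes onto distinct exit codes.
"""


class LexemoError(Exception):
    """Base class for all lexemo errors."""


class ConfigError(LexemoError):
    """Invalid run or generator configuration."""


class LexiconParseError(LexemoError):
    """A dictionary file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MalformedLexiconError(LexemoError):
    """A lexicon violates its structural invariants (unknown category,
    duplicate entry, cyclic hierarchy)."""


class EmptyParticipantError(LexemoError):
    """A participant has no countable tokens, so percentages are undefined."""


class PositionMismatchError(LexemoError):
    """A reference label points at a token position that does not exist."""


class UnknownSubcategoryError(LexemoError):
    """A reference label uses a subcategory outside the closed coding scheme."""


class UndefinedMetricError(LexemoError):
    """A diagnostic metric's denominator is zero."""


class DegenerateTestError(LexemoError):
    """A two-proportion test with pooled proportion 0 or 1 has no sampling
    variance and no defined z statistic."""


class UndefinedKappaError(LexemoError):
    """Chance agreement is 1, so Cohen's kappa is undefined."""


class UndefinedCorrelationError(LexemoError):
    """A constant column makes the Pearson correlation undefined."""


class StageFailure(LexemoError):
    """An end-to-end run failed at a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
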