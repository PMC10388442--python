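"""Exception hierarchy.

All package errors derive from :class:`DietScreenError` so callers can catch
one base class; specific subclasses carry enough context (column names, food
codes, row numbers) to make input problems actionable.
"""


class DietScreenError(Exception):
    """Base class for all dietscreen errors."""


class SchemaError(DietScreenError):
    """An input table is missing a required column or has an unparseable field."""


class RecordValidationError(DietScreenError):
    """A record violates an invariant (e.g. negative amount); carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class UnresolvedFoodError(DietScreenError):
    """Food codes referenced by recall records are absent from the composition table."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(f"food codes not in composition table: {', '.join(self.codes)}")


class MappingGapError(DietScreenError):
    """Foods present in a MOM table have no entry in the FFQ item map."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(f"food codes missing from FFQ item map: {', '.join(self.codes)}")


class UndefinedStatisticError(DietScreenError):
    """A contribution statistic is undefined (e.g. zero total intake)."""


class DegenerateVarianceError(DietScreenError):
    """Between-person variance of a nutrient total is zero; MOM2 is undefined."""


class ConfigurationError(DietScreenError):
    """A configuration file is malformed or incomplete."""


class ProfileMatchError(DietScreenError):
    """An intake has no matching person profile."""


class DegenerateSampleError(DietScreenError):
    """A statistical routine received a degenerate (e.g. constant or too small) sample."""


class EmptyReportError(DietScreenError):
    """A summary was requested over an empty input."""
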