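"""Exception types shared across the pipeline stages."""


class MvivError(Exception):
    """Base class for package errors."""


class SchemaError(MvivError):
    """An input table is missing a required column or has a bad layout."""

    exit_code = 2


class EmptySelectionError(MvivError):
    """A selection/harmonisation stage retained zero variants."""

    exit_code = 3


class EmptyResultError(MvivError):
    """A pipeline produced no analysable variant set."""

    exit_code = 3


class CollinearityError(MvivError):
    """A multivariable design matrix is (numerically) rank deficient."""

    def __init__(self, condition_number: float):
        self.condition_number = condition_number
        super().__init__(
            "multivariable design is rank deficient "
            f"(condition number {condition_number:.3g})"
        )
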