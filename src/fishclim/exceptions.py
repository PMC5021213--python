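"""Exception hierarchy for fishclim."""


class FishclimError(Exception):
    """Base class for all fishclim-specific errors."""


class InvalidArgumentError(FishclimError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(FishclimError, KeyError):
    """A table or grid is missing required columns/variables."""


class DegenerateDataError(FishclimError, ValueError):
    """Data cannot support the requested computation (e.g. one-class labels)."""


class UndefinedStatisticError(FishclimError, ValueError):
    """A statistic is undefined for the given input (e.g. AUC with one class)."""


class NoSkilledModelError(FishclimError, RuntimeError):
    """No candidate model passed the skill cutoff; an ensemble cannot be built."""


class ConfigError(FishclimError, ValueError):
    """A run configuration failed validation.

    ``errors`` holds one message per violated field, each prefixed with the
    field path.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
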