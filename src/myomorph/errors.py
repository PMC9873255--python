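"""Exception hierarchy shared across the pipeline."""


class MyomorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MyomorphError, ValueError):
    """An input configuration violates its invariants (bad design, missing channel, ...)."""


class DegenerateInputError(MyomorphError, ValueError):
    """The input is structurally valid but carries no usable signal
    (constant image, empty tissue mask, constant sample, ...)."""


class GenerationError(MyomorphError, RuntimeError):
    """The synthetic generator cannot realize the requested specification,
    e.g. an infeasible fiber packing."""


class InputError(MyomorphError, ValueError):
    """A numeric input is out of its physical domain (nonpositive mass, length, ...)."""


class ReconciliationError(MyomorphError, ValueError):
    """Tables that must share animal identifiers do not; carries the orphan ids."""

    def __init__(self, orphans):
        self.orphans = sorted(orphans)
        super().__init__(f"animal ids present in only one table: {self.orphans}")
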