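"""Exception hierarchy shared across the package."""


class CountersigError(Exception):
    """Base class for all package-specific errors."""


class MalformedIdentifierError(CountersigError, ValueError):
    """A gene identifier is empty or otherwise unusable."""


class MalformedInputError(CountersigError, ValueError):
    """A structured input file (TSV, GMT) violates its format contract."""


class SpeciesMismatchError(CountersigError, ValueError):
    """Two gene sets that must share a species tag do not."""


class ContainmentError(CountersigError, ValueError):
    """A foreground set is not contained in its background universe."""


class UndefinedTestError(CountersigError, ValueError):
    """A statistical test is requested on a degenerate (empty) universe."""


class InfeasibleConfigError(CountersigError, ValueError):
    """A synthetic-data configuration cannot be realised exactly."""
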