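"""Exception hierarchy shared across the package."""


class TdsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TdsError):
    """Invalid simulation or protocol parameters."""


class ScenarioError(TdsError):
    """A party scenario requests more cases/controls than are available."""


class NoVariationError(TdsError):
    """A genotype column is constant, so no association test is defined."""


class DegenerateOutcomeError(TdsError):
    """The phenotype vector (or a margin of a trend table) has one class only."""


class ProtocolError(TdsError):
    """A federation-protocol contract was violated."""


class FormatError(TdsError):
    """A genotype file could not be parsed in the declared dialect."""
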