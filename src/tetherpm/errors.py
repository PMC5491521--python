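"""Typed error taxonomy shared by all tetherpm modules."""


class TetherPMError(Exception):
    """Base class for all tetherpm errors."""


class InvalidArgumentError(TetherPMError, ValueError):
    """An argument value violates a function's precondition."""


class ConfigurationError(TetherPMError, ValueError):
    """A simulation configuration is internally inconsistent or infeasible."""


class DataError(TetherPMError, ValueError):
    """Input data do not satisfy the requirements of an analysis."""


class FormatError(TetherPMError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ContractViolationError(TetherPMError, RuntimeError):
    """An internal API contract was violated by the caller."""
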