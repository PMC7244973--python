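"""Exception hierarchy shared across the toolkit."""


class MTSError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MTSError):
    """Malformed input file (empty, ragged rows, duplicate headers)."""


class ConfigError(MTSError):
    """Invalid run or simulation configuration."""


class DegenerateDataError(MTSError):
    """Input reduced to an unusable state (e.g. every row removed)."""


class FitError(MTSError):
    """Reference space cannot be estimated from the given data."""


class RefinementError(MTSError):
    """Outlier screening left too few subjects to refit the space."""


class ContractError(MTSError):
    """Caller violated an operation precondition."""


class NumericError(MTSError):
    """Computation produced non-finite or inconsistent values."""
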