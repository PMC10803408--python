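"""Exception types shared across the package."""


class OigradError(Exception):
    """Base class for package-specific errors."""


class DegenerateInputError(OigradError, ValueError):
    """Input is numerically or structurally degenerate (constant column,
    singular covariance, near-zero eigenvalue)."""


class ContractError(OigradError, ValueError):
    """A caller violated an interface contract (overlapping subsets,
    identical indices, out-of-range order)."""


class OrderUnsupportedError(ContractError):
    """Requested gradient order too high for the system size: every
    O-information term in the expansion must involve at least two variables."""


class InsufficientDataError(OigradError, ValueError):
    """Too few records or samples for the requested statistical procedure."""
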