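"""Exception types shared across the package."""


class GeometryError(ValueError):
    """Raised when an acquisition geometry is infeasible or inconsistent."""


class ContractError(ValueError):
    """Raised when an operation's input violates its contract
    (shape mismatches, masks out of range, non-zero unacquired rows, ...)."""
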