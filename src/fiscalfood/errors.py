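"""Exception types shared across the package."""


class FiscalFoodError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(FiscalFoodError):
    """Raised when model dimensions fall below the supported minima."""


class InfeasibleBalanceError(FiscalFoodError):
    """Raised when a prior matrix admits no balanced counterpart.

    Carries the name of the offending account.
    """

    def __init__(self, account: str, message: str | None = None):
        self.account = account
        super().__init__(message or f"no balanced matrix exists: account {account!r} "
                         "has structurally zero receipts but positive payments (or vice versa)")


class ConvergenceError(FiscalFoodError):
    """Raised when an iterative solver fails; carries last residuals."""

    def __init__(self, message: str, residuals=None):
        self.residuals = residuals
        super().__init__(message)


class ClosureError(FiscalFoodError):
    """Raised for invalid macro-closure or policy configuration."""
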