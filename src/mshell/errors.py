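"""Exception types shared across the package."""


class ConstrictionLimitError(ValueError):
    """Raised when an intrinsic state reaches the constriction limit.

    The large-bending parameter eta measures half the intrinsic meridional
    curvature times the intrinsic thickness; |eta| -> 1 corresponds to fully
    wedge-shaped (constricted) cells, where one shell surface contracts to a
    point and the energy coefficients diverge like (1 - |eta|)^-2.  The
    theory is singular there, so evaluation is refused.
    """


class ConvergenceError(RuntimeError):
    """Raised when an iterative solve fails; carries the last iterate."""

    def __init__(self, message, last_iterate=None, diagnostics=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.diagnostics = diagnostics or {}
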