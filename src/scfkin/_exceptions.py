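"""Exception and warning types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class IdentifiabilityError(ValidationError):
    """More rate parameters requested than the data can constrain."""


class ConvergenceWarning(UserWarning):
    """An iterative fit terminated without meeting its convergence test."""


class OverConversionWarning(UserWarning):
    """A multi-turnover point converted more substrate than the initial-rate
    regime allows (fraction converted above 0.20)."""
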