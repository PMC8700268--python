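"""Exception types shared across the package."""


class FluomuxError(Exception):
    """Base class for all package errors."""


class ParameterError(FluomuxError, ValueError):
    """A single parameter is out of its physical or numerical range."""


class ConfigurationError(FluomuxError, ValueError):
    """An experiment configuration is internally inconsistent.

    May carry a list of all problems found (not just the first) in
    ``errors``; str() joins them.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class FitError(FluomuxError, RuntimeError):
    """A curve fit failed to converge or the data are degenerate.

    ``k_init`` carries the initializer's rate estimate when one exists.
    """

    def __init__(self, message, k_init=None):
        super().__init__(message)
        self.k_init = k_init
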