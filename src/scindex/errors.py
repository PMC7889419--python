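"""Exception hierarchy shared across the pipeline."""


class SCIndexError(Exception):
    """Base class for all scindex errors."""


class InvalidParameterError(SCIndexError, ValueError):
    """A physiological or numerical parameter is outside its valid range."""


class ConfigError(SCIndexError, ValueError):
    """A configuration is internally inconsistent (e.g. STFT geometry that
    does not produce the patch size the network expects)."""


class TooShortError(SCIndexError, ValueError):
    """Input signal is shorter than an operation requires."""


class DegenerateSignalError(SCIndexError, ValueError):
    """Signal has no variance (or another degeneracy) that makes an
    operation undefined; raised instead of emitting NaNs."""


class DegenerateLabelsError(SCIndexError, ValueError):
    """A label vector contains a single class where both are required."""


class LeakageError(SCIndexError, ValueError):
    """The same subject appears in more than one of train/validation/test."""
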