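"""Exception hierarchy shared across the package.

Every error raised by xtrait derives from :class:`XtraitError`, so callers can
catch one type at pipeline level while the subclasses keep the failure modes
distinguishable (bad configuration vs bad data vs a method that cannot run on
the data it was given).
"""


class XtraitError(Exception):
    """Base class for all xtrait errors."""


class ConfigurationError(XtraitError):
    """Invalid option, missing required column mapping, or malformed config."""


class InputError(XtraitError):
    """Input data unusable: zero parseable rows, empty filter result, etc."""


class DomainError(XtraitError, ValueError):
    """Argument outside its mathematical domain (e.g. eaf of 0 or 1)."""


class NumericalError(XtraitError):
    """Linear-algebra failure (singular system, non-PSD matrix)."""


class EstimationError(XtraitError):
    """An estimator cannot produce a meaningful result on these data."""


class InstrumentError(EstimationError):
    """No usable instrumental variables for a Mendelian-randomization run."""
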