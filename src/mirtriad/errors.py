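"""Exception hierarchy for the screening pipeline.

Every stage raises a subclass of :class:`MirtriadError` so the CLI can
abort with the stage name and cause while library users can catch the
specific failure mode.
"""


class MirtriadError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MirtriadError):
    """An invalid configuration value; the message names the field."""


class FormatError(MirtriadError):
    """A malformed input table; the message carries the offending cell."""


class NormalizationError(MirtriadError):
    """No usable housekeeper value for a sample."""


class ContrastError(MirtriadError):
    """A contrast references a group without a pooled sample."""


class ArgumentError(MirtriadError):
    """An operation was called with inconsistent arguments."""
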