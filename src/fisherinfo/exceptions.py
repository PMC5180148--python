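"""Exception hierarchy.

Everything user-facing raises :class:`FisherInfoError` (or a subclass) so the
CLI can map failures to a stage-named message and a nonzero exit code.
"""


class FisherInfoError(Exception):
    """Base class for all errors raised by this package."""


class InputError(FisherInfoError, ValueError):
    """Malformed or inconsistent input data (bad table, bad window, ...)."""


class ConfigError(FisherInfoError, ValueError):
    """Invalid run configuration; raised before any computation starts."""
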