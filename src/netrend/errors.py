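"""Exception hierarchy for netrend.

All package-raised failures derive from :class:`NetrendError` so callers
(and the CLI) can distinguish usage/data problems from genuine bugs.
"""


class NetrendError(Exception):
    """Base class for all netrend errors."""


class ParseError(NetrendError):
    """Malformed input file (ped/map/LD table)."""


class ConfigError(NetrendError):
    """Invalid parameter combination or out-of-range setting."""


class ComputationError(NetrendError):
    """A pipeline stage produced no usable result (e.g. no markers survive
    the MAF filter, no pairs fall in the distance window, no valid Ne bins)."""
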