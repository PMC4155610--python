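"""Exception hierarchy.

All validation and data errors raised by this package derive from
:class:`ProfileGridError`, so callers (and the CLI) can distinguish
data problems (exit 1) from usage problems (exit 2).
"""


class ProfileGridError(Exception):
    """Base class for all profilegrid data/validation errors."""


class AlignmentError(ProfileGridError):
    """Invalid alignment: unequal lengths, duplicate ids, bad symbols, empty input."""


class MetadataError(ProfileGridError):
    """Invalid metadata table: missing key column, duplicate keys, unknown column."""


class ProfileError(ProfileGridError):
    """Invalid profile operation: shape/alphabet mismatch, bad cell address."""


class StyleError(ProfileGridError):
    """Invalid style parameter: unknown scheme, out-of-range frequency, bad config."""
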