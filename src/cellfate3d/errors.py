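"""Exception hierarchy.

``UserError`` marks problems a user can fix (bad config, missing files);
the CLI maps it to exit code 1.  Everything else propagates as an internal
error (exit code 2).
"""


class CellFateError(Exception):
    """Base class for all package errors."""


class UserError(CellFateError):
    """Invalid configuration or input data."""


class ConfigError(UserError):
    """Malformed or inconsistent run configuration."""


class DatasetError(UserError):
    """Problems discovering or reading the image dataset."""


class NoContrastError(CellFateError):
    """A histogram with fewer than two occupied bins cannot be thresholded."""
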