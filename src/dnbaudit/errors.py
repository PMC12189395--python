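"""Exception hierarchy shared across the package.

``InputError`` and ``ConfigError`` map to the CLI exit codes 2 and 3.
"""


class DnbAuditError(Exception):
    """Base class for all package errors."""


class InputError(DnbAuditError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


class ConfigError(DnbAuditError):
    """Invalid configuration or parameters (CLI exit code 3)."""


class MgiNameError(InputError):
    """A read header does not match the configured MGI name grammar."""


class ForeignHeaderError(MgiNameError):
    """A read header carries no CxxRxx field-of-view token at all
    (e.g. an Illumina-style name)."""


class FovMismatchError(InputError):
    """An ordinal comparison was requested across different fields of view."""


class PairSyncError(InputError):
    """Mate files disagree on the read-name stem at some record index."""


class TruncationError(InputError):
    """Mate files contain different numbers of records."""
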