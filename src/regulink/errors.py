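"""Exception hierarchy shared across the package.

``DataFormatError`` covers malformed input files (bad BED/GTF/motif lines,
inconsistent tables); ``UsageError`` covers invalid parameter values supplied
through the API or CLI. The CLI maps these onto distinct exit codes.
"""


class RegulinkError(Exception):
    """Base class for all package-specific errors."""


class UsageError(RegulinkError, ValueError):
    """An argument or parameter value is outside its documented domain."""


class DataFormatError(RegulinkError, ValueError):
    """An input file or table violates its format contract."""
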