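"""Exception hierarchy.

``ConfigError`` maps to exit code 2 on the command line, ``DataError`` to 3.
"""


class SatArrayError(Exception):
    """Base class for all package errors."""


class ConfigError(SatArrayError):
    """Invalid configuration: unknown keys, out-of-range parameters."""


class DataError(SatArrayError):
    """Invalid or inconsistent input data."""


class BedFormatError(DataError):
    """Malformed BED/bedGraph/chrom.sizes line; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")
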