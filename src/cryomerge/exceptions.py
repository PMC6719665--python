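"""Exception hierarchy for cryomerge."""


class CryomergeError(Exception):
    """Base class for all cryomerge errors."""


class FormatError(CryomergeError):
    """A file could not be read as the expected format (bad header, truncation)."""


class UnsupportedModeError(FormatError):
    """MRC data mode is not a real-valued mode we can load."""


class StarParseError(FormatError):
    """A STAR file failed to parse (malformed loop, row width mismatch)."""


class StarDialectError(FormatError):
    """A STAR file uses the optics-group dialect, which is out of scope."""


class GridMismatchError(CryomergeError):
    """Two maps do not share box/pixel-size/origin; resample before comparing."""


class MergeError(CryomergeError):
    """STAR tables cannot be merged (missing column, incompatible scales)."""


class CalibrationWarning(UserWarning):
    """Non-fatal calibration issue (collapsed scan window, multi-modal score)."""
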