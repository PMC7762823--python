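"""Exception hierarchy for sheetctl."""


class SheetctlError(Exception):
    """Base class for all sheetctl errors."""


class ConfigurationError(SheetctlError, ValueError):
    """An acquisition configuration violates an invariant."""


class RangeError(SheetctlError, ValueError):
    """A commanded voltage would exceed the analogue output range.

    Raised before any samples are emitted; carries the channel name.
    """

    def __init__(self, channel: str, message: str):
        self.channel = channel
        super().__init__(f"[{channel}] {message}")


class CalibrationError(SheetctlError, ValueError):
    """A calibration procedure received unusable measurements."""


class EstimationError(SheetctlError, ValueError):
    """An automated estimator could not find a defensible answer."""
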