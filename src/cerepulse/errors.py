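"""Exception types shared across the pipeline stages."""


class CerepulseError(Exception):
    """Base class for pipeline errors."""


class NoBeatsDetectedError(CerepulseError):
    """No R-wave candidate exceeded the detection threshold."""


class UnusableChannelError(CerepulseError):
    """Artifact masking or QC removed every epoch of a channel."""


class DegenerateWaveformError(CerepulseError):
    """Waveform has no unique systolic peak (e.g. flat trace)."""


class InvertedWaveformError(CerepulseError):
    """Systolic value does not exceed the diastolic reference value."""


class EmptyRoiError(CerepulseError):
    """A region of interest resolved to zero usable units."""
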