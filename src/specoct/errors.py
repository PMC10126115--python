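"""Exception types shared across the package."""


class SpecOCTError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpecOCTError):
    """A scan container or results file is malformed or incomplete."""


class ValidationError(SpecOCTError):
    """A domain object violates one of its invariants."""


class CoverageError(SpecOCTError):
    """A spectrum or calibration does not cover the required wavelength span."""


class VesselRejected(SpecOCTError):
    """A vessel fails a structural acceptance rule (depth, decay, contrast)."""


class InsufficientData(SpecOCTError):
    """Too few B-scans survive quality control to measure a vessel."""


class NormalizationError(VesselRejected):
    """The amplitude at the normalization depth is unusable in some band."""


class DecayNotFound(VesselRejected):
    """No sustained blood-signal decay could be located in the depth profile."""
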