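"""Exception hierarchy for the registration toolkit."""


class FdctRegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FdctRegError):
    """A file does not conform to the expected on-disk format."""


class GeometryError(FdctRegError):
    """Volume geometry is invalid or unsupported (e.g. non-orthonormal direction)."""


class GeometryMismatchError(FdctRegError):
    """Two volumes that must share a grid do not; resample one onto the other first."""


class LandmarkError(FdctRegError):
    """Landmark sets are unusable: too few pairs, count mismatch, or degenerate layout."""


class NoOverlapError(FdctRegError):
    """Every metric sample mapped outside the moving volume; the transform is grossly wrong."""


class RegistrationError(FdctRegError):
    """The registration workflow could not produce a result."""


class PhantomSpecError(FdctRegError):
    """A phantom specification violates its geometric or statistical constraints."""
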