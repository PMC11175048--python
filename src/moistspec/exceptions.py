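"""Package-specific error types.

Plain ``ValueError`` is used for generic invalid arguments; the subclasses
below mark conditions callers may want to catch separately.
"""


class DegenerateInputError(ValueError):
    """Input is structurally valid but statistically degenerate (e.g. a
    constant spectrum fed to SNV, or a zero-variance response)."""


class GridMismatchError(ValueError):
    """Two spectra sets (or a set and a model) do not share a wavelength grid."""


class MissingSampleError(KeyError):
    """A requested sample id is absent from a spectra set or reference table."""


class ExcessFactorsError(ValueError):
    """More projection factors requested than the difference matrix supports."""


class UndefinedMetricError(ValueError):
    """A validation metric is undefined for the given inputs (e.g. RPIQ with
    zero RMSEP)."""
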