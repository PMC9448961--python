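"""Exception hierarchy for papwave.

All errors derive from :class:`PapwaveError` so callers can catch the
package's failures with one except clause; the subclasses mirror the
contract language used throughout the API (parameter vs input vs format).
"""


class PapwaveError(Exception):
    """Base class for all papwave errors."""


class ParameterError(PapwaveError, ValueError):
    """A configuration or model parameter violates its documented range."""


class InputError(PapwaveError, ValueError):
    """Input data violates a precondition (too short, empty, wrong shape)."""


class FormatError(PapwaveError, ValueError):
    """A file or in-memory container does not match the expected layout."""


class PairingError(PapwaveError, ValueError):
    """Two paired sequences (true vs predicted) cannot be aligned."""


class CIError(PapwaveError, ValueError):
    """A confidence interval cannot be computed (too few resampling units)."""
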