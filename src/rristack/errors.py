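"""Exception hierarchy for the rristack pipeline.

Every module raises subclasses of :class:`RristackError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class RristackError(Exception):
    """Base class for all rristack errors."""


# --- structio ---------------------------------------------------------------

class NoPolymerResidues(RristackError):
    """No polymer ATOM records survived parsing (e.g. HETATM-only file)."""


class UnknownChain(RristackError):
    """A requested chain identifier is absent from the coordinate file."""


class EmptyFile(RristackError):
    """A sequence file contained no records."""


class MalformedProfile(RristackError):
    """A PSI-BLAST ASCII profile did not match the expected column layout."""


class MappingFailure(RristackError):
    """Structure-to-sequence alignment identity fell below the floor."""


# --- features ---------------------------------------------------------------

class LengthMismatch(RristackError):
    """Profile length does not match the full-sequence length."""


class ToggleMismatch(RristackError):
    """Two residue vectors were built with different feature-family toggles."""


# --- dataset ----------------------------------------------------------------

class NoPositives(RristackError):
    """Undersampling requires at least one interacting pair."""


class NoAlignableChain(RristackError):
    """No chain pairing could be sequence-aligned for structural comparison."""


# --- models -----------------------------------------------------------------

class SingleClass(RristackError):
    """Training or evaluation requires both classes to be present."""


class NonFiniteFeature(RristackError):
    """A feature matrix contained NaN or infinite entries."""


class SchemaMismatch(RristackError):
    """Prediction-time feature width/order does not match the trained model."""


# --- synthgen ---------------------------------------------------------------

class DockingFailure(RristackError):
    """Synthetic docking could not hit the target interface size."""
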