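"""Exception hierarchy.

Every failure mode promised by the public API maps onto one of these, so
callers (and the CLI) can distinguish bad input from bad geometry from bad
parameters without string matching.
"""


class GlycoMDError(Exception):
    """Base class for all package errors."""


class PDBParseError(GlycoMDError):
    """Malformed PDB record; message names the offending line number."""


class EmptyInputError(GlycoMDError):
    """A file or collection that must be non-empty was empty."""


class TopologyMismatchError(GlycoMDError):
    """Frame atom count does not match the topology."""


class MissingParameterError(GlycoMDError):
    """Force-field parameters missing for one or more named atoms."""


class SelectionError(GlycoMDError):
    """Empty, overlapping or unknown atom selection."""


class SpecError(GlycoMDError):
    """Invalid synthetic-data specification."""


class GeometryError(GlycoMDError):
    """Degenerate geometry: overlapping atoms, collinear points, <3 points."""


class ParameterError(GlycoMDError):
    """Invalid analysis parameter (non-positive cutoff, bad window...)."""


class InsufficientSamplingError(GlycoMDError):
    """Too few frames/samples for the requested estimator."""


class PartitionError(GlycoMDError):
    """Ligand group partition has gaps or overlaps."""


class AssemblyError(GlycoMDError):
    """Inconsistent components handed to a report assembler."""
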