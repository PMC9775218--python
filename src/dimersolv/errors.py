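"""Exception hierarchy shared by all stages."""


class DimersolvError(Exception):
    """Base class for package errors."""


class ParseError(DimersolvError):
    """A file could not be parsed under the named dialect."""


class StructuralError(DimersolvError):
    """Topology/trajectory consistency violation (atom-count mismatch, missing box)."""


class UnsupportedFeatureError(DimersolvError):
    """Input requests a feature deliberately out of scope (e.g. triclinic boxes)."""


class SelectionError(DimersolvError):
    """Empty or invalid atom selection."""


class ConfigError(DimersolvError):
    """Invalid run configuration or window-series header."""


class DegenerateInputError(DimersolvError):
    """Numerically degenerate input (non-finite potential, zero-size sample)."""


class CapacityError(DimersolvError):
    """Requested solvent counts cannot be placed in the box."""


class ConnectivityError(DimersolvError):
    """Umbrella window histograms do not overlap into one connected component."""


class ConvergenceError(DimersolvError):
    """Self-consistent iteration failed to reach tolerance."""


class OverlapError(DimersolvError):
    """Forward/reverse sample distributions have no usable overlap."""


class GeometryError(DimersolvError):
    """Ill-conditioned geometry (near-coincident atoms, r_max beyond box)."""


class NoMinimumError(DimersolvError):
    """An RDF has no interior first minimum; an explicit cutoff is required."""


class ChainCountError(DimersolvError):
    """Operation requires exactly two peptide chains."""


class ParameterizationError(DimersolvError):
    """Nonbonded parameters missing for atoms in scope."""
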