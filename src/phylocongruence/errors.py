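"""Exception hierarchy shared across the package."""


class PhylocongruenceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhylocongruenceError, ValueError):
    """A file does not conform to its declared on-disk format."""


class SchemaError(FormatError):
    """A tabular input is missing required columns or keys."""


class AlignmentError(PhylocongruenceError, ValueError):
    """A sequence alignment violates its invariants."""


class DistanceError(PhylocongruenceError, ValueError):
    """A distance computation cannot proceed (e.g. no comparable sites)."""


class TreeError(PhylocongruenceError, ValueError):
    """Tree construction or manipulation failed."""


class CongruenceError(PhylocongruenceError, ValueError):
    """A congruence test is ill-posed for the given inputs."""


class SimulationError(PhylocongruenceError, ValueError):
    """A simulation configuration is invalid or infeasible."""
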