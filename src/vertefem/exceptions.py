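"""Exception hierarchy for the vertefem pipeline."""


class VertefemError(Exception):
    """Base class for all vertefem errors."""


class SizingError(VertefemError, ValueError):
    """Grid too small to contain the requested geometry (shell + caps)."""


class GeometryError(VertefemError, ValueError):
    """Requested defect geometry is not achievable inside the cortical shell."""


class StateError(VertefemError, RuntimeError):
    """Operation applied to a volume in the wrong state (e.g. augment without defect)."""


class MeshError(VertefemError, ValueError):
    """Volume cannot be meshed (no meshable voxels, missing embedding caps)."""


class SolverError(VertefemError, RuntimeError):
    """Linear system could not be solved (singular or non-converged)."""


class ConfigError(VertefemError, ValueError):
    """Inconsistent or incomplete run configuration."""


class DependencyError(VertefemError, LookupError):
    """A required upstream result (e.g. the 50%-defect fracture run) is missing."""


class DegenerateDataError(VertefemError, ValueError):
    """Statistical input is degenerate (zero variance, too few points)."""
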