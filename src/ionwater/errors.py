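"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`IonWaterError`
so callers can catch package errors without masking programming mistakes.
"""


class IonWaterError(Exception):
    """Base class for all ionwater errors."""


class FormatError(IonWaterError):
    """Malformed input file (XYZ, TSV, JSON). Message names the offending line/row."""


class TopologyError(IonWaterError):
    """Atoms cannot be partitioned into water monomers (wrong H/O counts, ambiguity)."""


class DegenerateGeometryError(IonWaterError):
    """Geometry that makes an operation undefined (coincident sites, ion at COM)."""


class DomainError(IonWaterError):
    """Argument outside the operation's domain (empty cluster, negative order)."""


class ConfigurationError(IonWaterError):
    """Missing or inconsistent configuration (no water model, unset weights)."""


class DataError(IonWaterError):
    """Inconsistent data values (reference energy below the declared minimum)."""


class FitError(IonWaterError):
    """Failure inside the fitting engine (rank deficiency, non-finite objective)."""


class SolverError(IonWaterError):
    """Induced-dipole solver did not converge; message reports the residual."""


class ModelError(IonWaterError):
    """Unphysical model regime, e.g. polarization catastrophe."""


class EvaluationError(IonWaterError):
    """Potential callback returned a non-finite energy during optimization."""
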