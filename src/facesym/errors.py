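"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation problems (bad inputs,
violated invariants) exit 2, I/O problems exit 3, degenerate geometry
(empty ROI, collinear landmarks) exits 4.
"""


class FacesymError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(FacesymError):
    """Input violates a documented precondition or invariant."""

    exit_code = 2


class FormatError(ValidationError):
    """A file parsed, but its content is not usable geometry."""


class MeshIOError(FacesymError):
    """File could not be read or written; message names the path."""

    exit_code = 3


class DegenerateGeometryError(FacesymError):
    """Geometry too degenerate to proceed (empty ROI, collinear basis)."""

    exit_code = 4


class EmptyRoiError(DegenerateGeometryError):
    """A crop or ROI selection produced no faces."""


class ConvergenceError(FacesymError):
    """Iterative fit failed to converge (e.g. perfect separation)."""

    exit_code = 2
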