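"""Exception hierarchy shared across the package."""


class CGNMRError(Exception):
    """Base class for all package-specific errors."""


class ParseError(CGNMRError):
    """A file could not be parsed; carries the offending line where known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class DialectError(CGNMRError):
    """File parsed, but does not conform to the expected dialect."""


class DuplicateKeyError(CGNMRError):
    """A table contains two entries for the same key."""


class ModelFormatError(CGNMRError):
    """A model-weight file is corrupted or structurally invalid."""


class LayoutMismatchError(CGNMRError):
    """Feature-layout version of a model does not match the featurizer."""


class DegenerateGeometryError(CGNMRError):
    """Angle/dihedral undefined for the given points (coincident/collinear)."""


class DegenerateInputError(CGNMRError):
    """A statistical routine received input it cannot operate on."""


class SimulationError(CGNMRError):
    """Integration or minimization failure; carries the step index."""

    def __init__(self, message, step=None):
        if step is not None:
            message = f"{message} (step {step})"
        super().__init__(message)
        self.step = step
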