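"""Exception types shared across the package."""


class EditBenchError(Exception):
    """Base class for all editbench-specific errors."""


class DesignError(EditBenchError, ValueError):
    """Invalid experimental design or design matrix."""


class ParameterError(EditBenchError, ValueError):
    """Invalid simulation or analysis parameter."""


class DegenerateDataError(EditBenchError, ValueError):
    """Input data too degenerate for the requested computation."""


class ConfoundingError(EditBenchError, ValueError):
    """Two factors are aliased and cannot be separated."""
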