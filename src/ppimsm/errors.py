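"""Exception hierarchy shared across the pipeline.

Exit codes: 2 config, 3 data, 4 numerical failure.
"""


class PipelineError(Exception):
    exit_code = 1


class ConfigError(PipelineError):
    exit_code = 2


class DataError(PipelineError):
    exit_code = 3


class NumericalError(PipelineError):
    exit_code = 4


class ReducibleMatrixError(NumericalError):
    """Transition matrix is not irreducible; MFPT / stationary vector undefined."""


class ComplexSpectrumError(NumericalError):
    """Dominant eigenvalues are complex; retry with a symmetrized analysis matrix."""


class DegenerateSubsetError(DataError):
    """Atom subset is collinear or too small to define a rigid-body fit."""
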