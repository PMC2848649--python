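"""Exception hierarchy for seqdbn."""


class SeqDBNError(Exception):
    """Base class for all seqdbn errors."""


class SpecError(SeqDBNError, ValueError):
    """A DBN specification is structurally invalid."""


class DataError(SeqDBNError, ValueError):
    """Sequence data is malformed or incompatible with a specification."""


class ParameterError(SeqDBNError, ValueError):
    """A distribution parameter violates its domain constraints."""


class EstimationError(SeqDBNError, RuntimeError):
    """A maximum-likelihood estimator failed (degenerate data, non-convergence)."""


class TopologyError(SeqDBNError, ValueError):
    """A network topology does not support the requested algorithm."""


class SerializationError(SeqDBNError, ValueError):
    """A state file is corrupted, truncated or of an unsupported version."""
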