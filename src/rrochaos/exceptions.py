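"""Exception hierarchy for rrochaos."""


class RROError(Exception):
    """Base class for all rrochaos errors."""


class NumericalInstabilityError(RROError):
    """An orbit left the admissible region (|x| beyond the divergence bound)."""


class StructureError(RROError):
    """The composite map lacks the interior extrema the analysis requires."""


class BracketingError(RROError):
    """A root search was requested on an interval that does not bracket a root."""


class DegenerateSignalError(RROError):
    """A correlation was requested against a constant signal or constant orbit."""


class EnsembleError(RROError):
    """Fewer than two valid trials survived in a trial ensemble."""


class EstimationError(RROError):
    """All perturbation segments of a Lyapunov estimate collapsed to zero."""


class ConfigError(RROError):
    """A run configuration failed validation."""
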