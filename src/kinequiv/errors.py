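"""Exception hierarchy shared across the package."""


class KinequivError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KinequivError):
    """A model file could not be parsed; the message names the offending record."""


class ModelValidationError(KinequivError):
    """A model violates a structural invariant (duplicate ids, bad bounds, ...)."""


class NestingError(KinequivError):
    """Two models are not nested: a core reaction of the small model has no
    counterpart in the large one."""


class ConfigurationError(KinequivError):
    """Inconsistent or incomplete configuration (missing dG0, unknown ids, ...)."""


class UnknownPresetError(ConfigurationError):
    """Directionality preset name not registered; message lists known presets."""


class InfeasibleProblemError(KinequivError):
    """An optimisation problem has no feasible point under the given constraints."""


class SolverError(KinequivError):
    """The LP/MILP solver terminated abnormally."""


class NearEquilibriumError(KinequivError):
    """A reaction sits too close to thermodynamic equilibrium for elasticities to
    be finite."""


class GenerationError(KinequivError):
    """A synthetic model family specification could not be realised."""
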