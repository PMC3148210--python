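"""Exception hierarchy shared across the pipeline stages."""


class TagPowerError(Exception):
    """Base class for all package errors."""


class FormatError(TagPowerError):
    """Malformed or unsupported input record (e.g. multiallelic site)."""


class PhasingError(FormatError):
    """Genotype present but not phased."""


class MissingGenotypeError(FormatError):
    """Missing genotype call; imputation is out of scope, so this is fatal."""


class DomainError(TagPowerError, ValueError):
    """Argument outside its mathematical domain."""


class LookupError_(TagPowerError, KeyError):
    """Reference to an unknown sample or variant."""


class ConfigError(TagPowerError):
    """Invalid or infeasible configuration."""


class GenerationError(TagPowerError):
    """Synthetic generation produced nothing usable (e.g. no polymorphism)."""


class ConsistencyError(TagPowerError):
    """Inputs that must agree (panel/assignment, penetrance/prevalence) do not."""


class InfeasibleModelError(TagPowerError):
    """Disease model parameters imply a penetrance outside [0, 1]."""


class SimulationError(TagPowerError):
    """Monte-Carlo sampling exhausted its attempt budget."""


class DegenerateTableError(TagPowerError):
    """Contingency table with fewer than two informative genotype columns."""
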