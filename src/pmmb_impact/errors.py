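"""Exception hierarchy; the CLI maps each class to a distinct exit code."""


class PmmbImpactError(Exception):
    """Base class for all package errors."""


class ConfigError(PmmbImpactError):
    """Bad configuration: unknown convention, malformed rules file, ..."""


class DomainError(PmmbImpactError):
    """Input outside an operation's domain (negative wage, percent > 100)."""


class ValidationError(PmmbImpactError):
    """Structurally invalid data (inconsistent schedule, infeasible spec)."""


class InfeasibleSpecError(ValidationError):
    """A synthetic-roster spec whose constraints cannot all be met; the
    message names the violated constraint."""


class NumericalError(PmmbImpactError):
    """A numerical procedure failed to converge."""
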