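"""Exception hierarchy.

All package-specific failures derive from :class:`WntGradError` so callers can
catch one base class; the subclasses distinguish bad user input
(:class:`ConfigurationError`, :class:`DomainError`) from internal consistency
violations (:class:`IntegrityError`) and numerical failure of the stiff
integrator (:class:`SolverError`).
"""


class WntGradError(Exception):
    """Base class for all errors raised by wntgrad."""


class ConfigurationError(WntGradError, ValueError):
    """Invalid parameter set, scenario, grid or config file."""


class DomainError(WntGradError, ValueError):
    """Argument outside its mathematical domain (e.g. x beyond the field)."""


class IntegrityError(WntGradError, RuntimeError):
    """Internal state violates a structural contract (NaN, shape mismatch...)."""


class SolverError(WntGradError, RuntimeError):
    """The stiff integrator failed to produce an acceptable trajectory."""
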