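"""Exception hierarchy shared across the package."""


class FluxshiftError(Exception):
    """Base class for all package-specific errors."""


class ModelValidationError(FluxshiftError):
    """A metabolic model violates a structural invariant.

    Carries ``offending_ids``, the list of element ids that triggered the
    failure (e.g. dangling metabolite references).
    """

    def __init__(self, message: str, offending_ids: list[str] | None = None):
        super().__init__(message)
        self.offending_ids = offending_ids or []


class FormatError(FluxshiftError):
    """A model file could not be parsed; names the offending element."""


class UnknownReactionError(FluxshiftError, KeyError):
    """A reaction id was not found in the model."""

    def __init__(self, reaction_id: str):
        super().__init__(f"unknown reaction id: {reaction_id!r}")
        self.reaction_id = reaction_id


class BoundError(FluxshiftError, ValueError):
    """A lower flux bound exceeds the corresponding upper bound."""


class ConfigurationError(FluxshiftError):
    """A run configuration or solver setup is invalid (e.g. empty objective)."""


class ContractError(FluxshiftError):
    """An operation was called with inputs that break its contract
    (non-finite fluxes, non-optimal distributions, dimension mismatch)."""


class PipelineError(FluxshiftError):
    """A pipeline stage failed irrecoverably (e.g. infeasible wild type)."""
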