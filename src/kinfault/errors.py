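"""Exception hierarchy shared across the package."""


class KinfaultError(Exception):
    """Base class for all package-specific errors."""


class ModelValidationError(KinfaultError):
    """A kinetic model violates one of its structural invariants."""


class UnknownTargetError(KinfaultError):
    """A perturbation names a rate constant or species the model lacks."""


class NotPreexistingError(KinfaultError):
    """A molecule perturbation targets a species with zero initial concentration.

    Only species present before stimulation ("preexisting") are admissible
    targets for abundance faults.
    """


class IntegrationError(KinfaultError):
    """The ODE solver failed; carries the failure time and state norm."""

    def __init__(self, message: str, t_fail: float | None = None,
                 state_norm: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail
        self.state_norm = state_norm


class GridMismatchError(KinfaultError):
    """Two profiles that must share a time grid do not."""


class UndefinedSimilarityError(KinfaultError):
    """Similarity is undefined (zero-norm or nonpositive-mean profile)."""


class SbmlImportError(KinfaultError):
    """The SBML document could not be mapped onto the model contract."""
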