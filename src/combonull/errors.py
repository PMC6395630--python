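"""Exception hierarchy.

Undefined regions of a null model (Loewe beyond the shared effect range,
Tallarida with an inexpressible equivalent dose) are scientific content, not
numeric accidents, so they carry structured payloads rather than bare messages.
"""


class CombonullError(Exception):
    """Base class for all package errors."""


class DoseDomainError(CombonullError, ValueError):
    """A dose was negative or non-finite."""


class EffectOutOfRangeError(CombonullError, ValueError):
    """An effect level lies outside the curve's open range (e_min, e_max).

    Attributes
    ----------
    boundary : str
        ``"below_min"`` or ``"above_max"``.  The ``above_max`` case drives
        the partial-agent logic downstream.
    """

    def __init__(self, message: str, *, boundary: str):
        super().__init__(message)
        self.boundary = boundary


class LoeweUndefinedError(CombonullError):
    """No effect level below min(e_max_a, e_max_b) solves the Loewe equation.

    Attributes
    ----------
    limit_level : float
        The limiting effect level min(e_max_a, e_max_b); the Loewe model is
        undefined for effects at or above it.
    """

    def __init__(self, message: str, *, limit_level: float):
        super().__init__(message)
        self.limit_level = limit_level


class EquivalentDoseUndefinedError(CombonullError):
    """A Tallarida equivalent dose does not exist: the target curve saturates
    below the source effect.

    Attributes
    ----------
    saturating : str
        ``"a"`` or ``"b"`` — which curve of the pair saturates.
    """

    def __init__(self, message: str, *, saturating: str):
        super().__init__(message)
        self.saturating = saturating


class UnderdeterminedFitError(CombonullError, ValueError):
    """Fewer distinct doses than free parameters."""


class UnnormalisedEffectError(CombonullError, ValueError):
    """Bliss requires e_min = 0 and the larger e_max = 1."""


class QuadratureError(CombonullError, RuntimeError):
    """Hand-model quadrature or inversion failed to reach tolerance."""


class IsoboleError(CombonullError):
    """The requested effect level is unattainable on every ray."""
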