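"""Structural model parameter sets.

Units follow the clinical convention used throughout the package:
time in minutes from induction, volumes in litres, clearances in
L/min, rate constants in min^-1, concentrations in mg/L and
depth-of-anesthesia indices on their native 0-99 scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


class InvalidParameterError(ValueError):
    """A structural parameter violates its positivity/range constraint."""


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment disposition parameters.

    Attributes
    ----------
    CL : float
        Elimination clearance from the central compartment, L/min.
    Q : float
        Inter-compartmental clearance, L/min.
    V1 : float
        Central volume of distribution, L.
    V2 : float
        Peripheral volume of distribution, L.
    """

    CL: float
    Q: float
    V1: float
    V2: float

    def __post_init__(self) -> None:
        for name in ("CL", "Q", "V1", "V2"):
            v = getattr(self, name)
            if not (v > 0.0) or not (v < float("inf")):
                raise InvalidParameterError(
                    f"PK parameter {name} must be strictly positive and finite, got {v!r}"
                )

    def replace(self, **kw) -> "PKParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class BiophaseParameters:
    """Effect-site (biophase) distribution constants.

    ``order=1`` is the classical single effect compartment
    dCe/dt = ke0*(Cb - Ce).  ``order=2`` adds a peripheral effect
    compartment exchanging with the central effect site at rates
    ke12 (central -> peripheral) and ke21 (back).
    """

    ke0: float
    ke12: float = 0.0
    ke21: float = 0.0
    order: int = 1

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise InvalidParameterError(f"biophase order must be 1 or 2, got {self.order}")
        if not (self.ke0 > 0.0):
            raise InvalidParameterError(f"ke0 must be strictly positive, got {self.ke0!r}")
        if self.order == 1:
            if self.ke12 != 0.0 or self.ke21 != 0.0:
                raise InvalidParameterError("order=1 biophase requires ke12 = ke21 = 0")
        else:
            if not (self.ke12 > 0.0 and self.ke21 > 0.0):
                raise InvalidParameterError(
                    "order=2 biophase requires strictly positive ke12 and ke21; "
                    "use order=1 for the reduced model"
                )

    @property
    def n_states(self) -> int:
        return self.order


@dataclass(frozen=True)
class PDParameters:
    """Inhibitory sigmoid Emax parameters for an anesthesia depth index.

    The response is E(ce) = E0 - Emax * ce**gamma / (EC50**gamma + ce**gamma),
    decreasing from the awake baseline E0 towards the floor E0 - Emax.
    """

    E0: float
    Emax: float
    EC50: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.E0 <= 100.0):
            raise InvalidParameterError(f"E0 must lie in (0, 100], got {self.E0!r}")
        if not (0.0 < self.Emax <= self.E0):
            raise InvalidParameterError(
                f"Emax must lie in (0, E0]; floor E0-Emax must be >= 0 (E0={self.E0}, Emax={self.Emax})"
            )
        if not (self.EC50 > 0.0):
            raise InvalidParameterError(f"EC50 must be strictly positive, got {self.EC50!r}")
        if not (self.gamma > 0.0):
            raise InvalidParameterError(f"gamma must be strictly positive, got {self.gamma!r}")

    @property
    def floor(self) -> float:
        """Deepest attainable index value E0 - Emax."""
        return self.E0 - self.Emax
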