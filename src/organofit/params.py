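"""Parameter containers for the four-compartment tumor-microenvironment model.

The model tracks four cell subpopulations of an NSCLC organoid — cancer cells
(``N``, PD-L1+), M2-polarized macrophages (``M2``, CD206+), cancer-associated
fibroblasts (``CAF``, aSMA+) and cytotoxic T cells (``Tc``, CD8+).  Seven
interaction rates are fixed from the literature (:class:`KnownParameters`);
the remaining eight are estimated from time-course measurements
(:class:`EstimatedParameters`).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

import numpy as np

from .exceptions import InvalidStateError

#: Fixed compartment order used everywhere: z = (N, M2, CAF, Tc).
COMPARTMENTS: tuple[str, ...] = ("N", "M2", "CAF", "Tc")

#: Fixed order of the estimated parameters; shared with the columns of the
#: least-squares design matrix.
ESTIMATED_ORDER: tuple[str, ...] = (
    "q2", "q4", "q5", "q6", "delta_CAF", "q7", "q8", "q9",
)


@dataclass(frozen=True)
class KnownParameters:
    """Literature-fixed rates of the model.

    Defaults are the adjusted literature values.  Units: ``gamma``,
    ``delta_M2``, ``delta_Tc`` are plain rates (day^-1); ``K`` is an
    abundance (same units as the state); ``q1``, ``q3``, ``k`` are per-cell
    rates (day^-1 per state unit).

    Attributes
    ----------
    gamma : float
        Cancer-cell logistic growth rate.
    K : float
        Cancer-cell carrying capacity.
    q1 : float
        Stimulation of cancer cells by M2 macrophages.
    q3 : float
        Stimulation of M2 macrophages by cancer cells.
    delta_M2 : float
        Natural death rate of M2 macrophages.
    k : float
        Per-T-cell kill rate of cancer cells.
    delta_Tc : float
        Natural death rate of cytotoxic T cells.
    """

    gamma: float = 0.05
    K: float = 1.0e6
    q1: float = 4.0e-5
    q3: float = 4.0e-8
    delta_M2: float = 0.2
    k: float = 1.0e-3
    delta_Tc: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"known parameter {f.name!r} must be finite and > 0, got {v!r}"
                )

    def replace(self, **overrides: float) -> "KnownParameters":
        from dataclasses import replace as _replace

        return _replace(self, **overrides)


@dataclass(frozen=True)
class EstimatedParameters:
    """The eight fitted interaction rates, in the fixed order
    ``(q2, q4, q5, q6, delta_CAF, q7, q8, q9)``.

    ``q2``: CAF -> cancer stimulation; ``q4``: CAF -> M2 stimulation;
    ``q5``: cancer -> CAF stimulation; ``q6``: M2 -> CAF stimulation;
    ``delta_CAF``: CAF death rate; ``q7``: cancer -> Tc stimulation;
    ``q8``: M2 -> Tc suppression; ``q9``: CAF -> Tc suppression.

    All components are constrained to be nonnegative.
    """

    q2: float = 0.0
    q4: float = 0.0
    q5: float = 0.0
    q6: float = 0.0
    delta_CAF: float = 0.0
    q7: float = 0.0
    q8: float = 0.0
    q9: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"estimated parameter {f.name!r} must be finite and >= 0, got {v!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in ESTIMATED_ORDER], dtype=float)

    @classmethod
    def from_array(cls, q: Iterable[float]) -> "EstimatedParameters":
        q = np.asarray(list(q), dtype=float)
        if q.shape != (len(ESTIMATED_ORDER),):
            raise ValueError(f"expected {len(ESTIMATED_ORDER)} components, got {q.shape}")
        return cls(**dict(zip(ESTIMATED_ORDER, q)))

    def replace(self, **overrides: float) -> "EstimatedParameters":
        from dataclasses import replace as _replace

        return _replace(self, **overrides)


@dataclass(frozen=True)
class StateVector:
    """Abundances of the four compartments at one instant, order (N, M2, CAF, Tc)."""

    N: float
    M2: float
    CAF: float
    Tc: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise InvalidStateError(
                    f"compartment {f.name!r} must be finite and >= 0, got {v!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([self.N, self.M2, self.CAF, self.Tc], dtype=float)

    @classmethod
    def from_array(cls, z: Iterable[float]) -> "StateVector":
        z = np.asarray(list(z), dtype=float)
        if z.shape != (4,):
            raise InvalidStateError(f"state must have 4 components, got shape {z.shape}")
        return cls(*z)


def as_state_array(state) -> np.ndarray:
    """Coerce a :class:`StateVector` or 4-sequence to a validated float array."""
    if isinstance(state, StateVector):
        return state.to_array()
    z = np.asarray(state, dtype=float)
    if z.shape != (4,):
        raise InvalidStateError(f"state must have 4 components, got shape {z.shape}")
    if not np.all(np.isfinite(z)):
        raise InvalidStateError(f"state has non-finite components: {z}")
    if np.any(z < 0):
        raise InvalidStateError(f"state has negative components: {z}")
    return z
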