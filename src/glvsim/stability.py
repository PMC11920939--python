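"""Local stability of the interior equilibrium from the Jacobian spectrum.

At an interior equilibrium of the generalized Lotka-Volterra system the
bracket ``r_i + sum_j a_ij N_j`` vanishes for every species, so the Jacobian
collapses to the closed form ``J = diag(N*) A``.  The equilibrium is locally
stable iff every eigenvalue of ``J`` has negative real part; this spectral
test is equivalent to the Routh-Hurwitz conditions on the characteristic
polynomial and is numerically robust for the matrix sizes used here
(S up to a few hundred).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError
from .sampling import interaction_entries

__all__ = ["StabilityReport", "jacobian_at_equilibrium", "is_locally_stable",
           "DEFAULT_STABILITY_TOL"]

#: Eigenvalues whose real part is within this band of zero are flagged
#: marginal rather than silently classified: exact zeros have measure zero
#: under the sampling scheme, but floating point does not.
DEFAULT_STABILITY_TOL = 1e-9


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalue spectrum of the Jacobian and the stability verdict."""

    eigenvalues: np.ndarray
    max_real_part: float
    is_stable: bool
    is_marginal: bool


def jacobian_at_equilibrium(A, Nstar: np.ndarray) -> np.ndarray:
    """Jacobian diag(N*) A of the GLV system at its interior equilibrium."""
    entries = interaction_entries(A)
    Nstar = np.asarray(Nstar, dtype=float)
    if Nstar.ndim != 1 or Nstar.shape[0] != entries.shape[0]:
        raise DimensionMismatchError(
            f"equilibrium of length {Nstar.shape} does not match matrix "
            f"of shape {entries.shape}")
    return Nstar[:, None] * entries


def is_locally_stable(J: np.ndarray,
                      stability_tol: float = DEFAULT_STABILITY_TOL) -> StabilityReport:
    """Spectral local-stability test: stable iff max Re(lambda) < -tol."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise DimensionMismatchError(f"Jacobian must be square, got {J.shape}")
    eigenvalues = np.linalg.eigvals(J)
    max_real_part = float(eigenvalues.real.max())
    return StabilityReport(
        eigenvalues=eigenvalues,
        max_real_part=max_real_part,
        is_stable=bool(max_real_part < -stability_tol),
        is_marginal=bool(abs(max_real_part) <= stability_tol),
    )
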