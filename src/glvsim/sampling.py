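"""Random generation of interaction webs, equilibria and perturbations.

The community-construction recipe is: draw a per-capita interaction matrix
``A`` (diagonal fixed at -1, a prescribed number of nonzero off-diagonal
entries with Gaussian strengths), draw a strictly positive equilibrium
abundance vector ``N*`` (lognormal), and then *define* the intrinsic growth
rates as ``r = -A N*`` so that ``N*`` is an interior equilibrium of the
generalized Lotka-Volterra system by construction. Initial conditions are
small Gaussian perturbations of ``N*``, reflected to stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig
from .errors import (DimensionMismatchError, InvalidConnectanceError,
                     InvalidRichnessError)

__all__ = [
    "InteractionMatrix",
    "n_links",
    "sample_interaction_matrix",
    "sample_equilibrium",
    "growth_rates_from_equilibrium",
    "perturb",
    "interaction_entries",
]


@dataclass(frozen=True)
class InteractionMatrix:
    """An S x S per-capita interaction matrix with fixed -1 diagonal.

    ``entries[i, j]`` is the effect of species ``j`` on the per-capita
    growth rate of species ``i`` (units: 1 / (abundance * time)).
    """

    entries: np.ndarray

    @property
    def S(self) -> int:
        return self.entries.shape[0]

    @property
    def connectance_realized(self) -> int:
        """Number of nonzero off-diagonal entries."""
        off = ~np.eye(self.S, dtype=bool)
        return int(np.count_nonzero(self.entries[off]))


def interaction_entries(A) -> np.ndarray:
    """Coerce an :class:`InteractionMatrix` or array-like to a 2-D float array."""
    entries = np.asarray(getattr(A, "entries", A), dtype=float)
    if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
        raise DimensionMismatchError(
            f"interaction matrix must be square, got shape {entries.shape}")
    return entries


def n_links(S: int, c: float) -> int:
    """Exact number of nonzero off-diagonal entries: round(c*S*(S-1)).

    Rounding is half-away-from-zero, so e.g. S=10, c=0.7 gives 63.
    """
    return int(np.floor(c * S * (S - 1) + 0.5))


def sample_interaction_matrix(config: ScenarioConfig,
                              rng: np.random.Generator) -> InteractionMatrix:
    """Draw a random interaction matrix for the given scenario.

    Exactly ``n_links(S, c)`` off-diagonal positions, chosen uniformly
    without replacement, receive independent N(0, sigma^2) draws.  Under a
    sign-constrained mode the draw magnitudes are kept (half-Gaussian) and
    the scenario sign is applied.  All other off-diagonal entries are exactly
    zero and the diagonal is exactly -1.
    """
    S, c = config.S, config.c
    if S < 2:
        raise InvalidRichnessError(f"need at least 2 species, got S={S}")
    if not 0.0 <= c <= 1.0:
        raise InvalidConnectanceError(f"connectance must lie in [0, 1], got {c}")

    k = n_links(S, c)
    A = np.zeros((S, S))
    if k > 0:
        # off-diagonal slots in row-major order, skipping the diagonal
        flat = rng.choice(S * (S - 1), size=k, replace=False)
        rows = flat // (S - 1)
        cols = flat % (S - 1)
        cols = cols + (cols >= rows)
        draws = rng.normal(0.0, config.sigma, size=k)
        if config.sign_mode == "all_negative":
            draws = -np.abs(draws)
        elif config.sign_mode == "all_positive":
            draws = np.abs(draws)
        A[rows, cols] = draws
    np.fill_diagonal(A, -1.0)
    return InteractionMatrix(entries=A)


def sample_equilibrium(S: int, rng: np.random.Generator) -> np.ndarray:
    """Draw equilibrium abundances with ln(N_i*) ~ N(0, 1), i.i.d.

    The resulting lognormal has median 1 and mean e^(1/2) ~= 1.6487.
    """
    if int(S) != S or S < 1:
        raise InvalidRichnessError(f"S must be a positive integer, got {S}")
    return np.exp(rng.standard_normal(int(S)))


def growth_rates_from_equilibrium(A, Nstar: np.ndarray) -> np.ndarray:
    """Intrinsic growth rates r = -A N* making N* an interior equilibrium.

    The returned vector satisfies ``A @ Nstar + r == 0`` exactly (the same
    floating-point product is negated), so the equilibrium residual of the
    assembled model is zero to the last bit.
    """
    entries = interaction_entries(A)
    Nstar = np.asarray(Nstar, dtype=float)
    if Nstar.ndim != 1 or Nstar.shape[0] != entries.shape[0]:
        raise DimensionMismatchError(
            f"equilibrium vector of length {Nstar.shape} does not match "
            f"matrix of shape {entries.shape}")
    return -(entries @ Nstar)


def perturb(Nstar: np.ndarray, perturb_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    """Perturbed initial state N_p,i = |N_i* + eps_i|, eps_i ~ N(0, sd^2).

    The absolute value guards against the rare negative abundance produced
    when a small equilibrium entry receives a large negative shock.
    """
    if perturb_sd < 0:
        raise ValueError("perturb_sd must be >= 0")
    Nstar = np.asarray(Nstar, dtype=float)
    return np.abs(Nstar + rng.normal(0.0, perturb_sd, size=Nstar.shape))
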