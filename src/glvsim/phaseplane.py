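"""Two-species phase-plane analysis of the original and bounded models.

For a pair of self-limited species (``a11, a22 < 0``) the original
Lotka-Volterra system has at most four equilibria: the origin, two
single-species boundary points and the interior intersection of the
nontrivial isoclines.  Strong mutualism (``a12 a21 > a11 a22``) turns the
interior point into a saddle, and trajectories escaping along its unstable
manifold blow up.  The bounded model adds *ceiling* equilibria in which one
or both species sit exactly at ``Nmax`` (where the attenuation factor
vanishes); for strong mutualism the double-ceiling point ``(Nmax, Nmax)``
is the stable state that replaces the blow-up.

Ceiling equilibria are located analytically: with ``N_i = Nmax`` fixed, the
partner equation vanishes either at zero, at its ceiling, or where its own
bracket ``r_j + a_j1 N_1 + a_j2 N_2`` is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .stability import DEFAULT_STABILITY_TOL

__all__ = ["TwoSpeciesModel", "EquilibriumPoint", "interior_equilibrium",
           "enumerate_equilibria", "vector_field_grid", "isocline_polylines"]

_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class TwoSpeciesModel:
    """A two-species Lotka-Volterra model, optionally bounded at Nmax."""

    r1: float
    r2: float
    a11: float
    a12: float
    a21: float
    a22: float
    Nmax: Optional[float] = None

    def __post_init__(self) -> None:
        if self.a11 >= 0 or self.a22 >= 0:
            raise ValueError("self-limitation requires a11 < 0 and a22 < 0")
        if self.Nmax is not None and self.Nmax <= 0:
            raise ValueError("Nmax must be positive")

    @property
    def bounded(self) -> bool:
        return self.Nmax is not None

    @property
    def A(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])

    @property
    def r(self) -> np.ndarray:
        return np.array([self.r1, self.r2])

    def rhs(self, N: np.ndarray) -> np.ndarray:
        N = np.asarray(N, dtype=float)
        growth = N * (self.r + self.A @ N)
        if self.bounded:
            growth *= (self.Nmax - N) / self.Nmax
        return growth

    def jacobian(self, N: np.ndarray) -> np.ndarray:
        """Jacobian of the governing (bounded or unbounded) system at any N."""
        N = np.asarray(N, dtype=float)
        bracket = self.r + self.A @ N
        if not self.bounded:
            J = N[:, None] * self.A
            J[np.diag_indices_from(J)] += bracket
            return J
        phi = (self.Nmax - N) / self.Nmax
        J = (N * phi)[:, None] * self.A
        J[np.diag_indices_from(J)] += bracket * phi - N * bracket / self.Nmax
        return J


@dataclass(frozen=True)
class EquilibriumPoint:
    """A rest point of the two-species system with its linear classification."""

    coordinates: tuple[float, float]
    kind: str       # "trivial" | "boundary" | "interior" | "ceiling"
    stability: str  # "stable" | "unstable" | "saddle" | "marginal"
    eigenvalues: tuple[complex, complex]
    degenerate: bool = False


def _classify(model: TwoSpeciesModel, N: np.ndarray,
              tol: float = DEFAULT_STABILITY_TOL) -> tuple[str, np.ndarray]:
    eig = np.linalg.eigvals(model.jacobian(N))
    re = eig.real
    if np.any(np.abs(re) <= tol):
        return "marginal", eig
    if np.all(re < 0):
        return "stable", eig
    if np.all(re > 0):
        return "unstable", eig
    return "saddle", eig


def _kind(N: np.ndarray, Nmax: Optional[float]) -> str:
    at_zero = N == 0.0
    if at_zero.all():
        return "trivial"
    if Nmax is not None and np.any(N == Nmax):
        return "ceiling"
    if at_zero.any():
        return "boundary"
    return "interior"


def _make_point(model: TwoSpeciesModel, N: np.ndarray,
                degenerate: bool = False) -> EquilibriumPoint:
    stability, eig = _classify(model, N)
    return EquilibriumPoint(
        coordinates=(float(N[0]), float(N[1])),
        kind=_kind(N, model.Nmax),
        stability=stability,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        degenerate=degenerate,
    )


def interior_equilibrium(model: TwoSpeciesModel) -> Optional[EquilibriumPoint]:
    """Intersection of the nontrivial isoclines, if strictly positive.

    Solves ``r + A N = 0``; returns None when the isoclines are parallel
    (singular ``A``) or the intersection is not strictly positive.  For a
    bounded model the point must also lie strictly below the ceiling.
    """
    A, r = model.A, model.r
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-14 * max(1.0, float(np.abs(A).max()) ** 2):
        return None
    N = np.linalg.solve(A, -r)
    if np.any(N <= 0):
        return None
    if model.bounded and np.any(N >= model.Nmax):
        return None
    return _make_point(model, N)


def enumerate_equilibria(model: TwoSpeciesModel) -> list[EquilibriumPoint]:
    """All equilibria of the governing system, each classified.

    Always includes the origin; includes single-species carrying-capacity
    points when positive; the interior point when feasible; and, for a
    bounded model, every ceiling combination (one species pinned at Nmax
    with the partner at zero, at its conditional rest point, or also at
    Nmax).
    """
    points: list[np.ndarray] = [np.zeros(2)]

    K1 = -model.r1 / model.a11
    K2 = -model.r2 / model.a22
    if K1 > 0 and not (model.bounded and K1 >= model.Nmax):
        points.append(np.array([K1, 0.0]))
    if K2 > 0 and not (model.bounded and K2 >= model.Nmax):
        points.append(np.array([0.0, K2]))

    interior = interior_equilibrium(model)
    if interior is not None:
        points.append(np.array(interior.coordinates))

    if model.bounded:
        M = model.Nmax
        points.append(np.array([M, 0.0]))
        points.append(np.array([0.0, M]))
        points.append(np.array([M, M]))
        # species 1 pinned at the ceiling; partner bracket root
        y = -(model.r2 + model.a21 * M) / model.a22
        if 0.0 < y < M:
            points.append(np.array([M, y]))
        x = -(model.r1 + model.a12 * M) / model.a11
        if 0.0 < x < M:
            points.append(np.array([x, M]))

    out: list[EquilibriumPoint] = []
    seen: list[np.ndarray] = []
    for N in points:
        if any(np.allclose(N, p, atol=1e-12) for p in seen):
            continue
        seen.append(N)
        residual = float(np.abs(model.rhs(N)).max())
        scale = max(1.0, float(np.abs(N).max())) * max(
            1.0, float(np.abs(model.A).max()), float(np.abs(model.r).max()))
        if residual > _RESIDUAL_TOL * scale:
            raise AssertionError(
                f"candidate equilibrium {N} has residual {residual:.3e}")
        out.append(_make_point(model, N))
    return out


def vector_field_grid(model: TwoSpeciesModel,
                      N1_range: tuple[float, float],
                      N2_range: tuple[float, float],
                      resolution: int = 20) -> pd.DataFrame:
    """Evaluate dN/dt on a regular grid; rows ordered lexicographically.

    Columns: ``N1, N2, dN1_dt, dN2_dt``; ``resolution**2`` rows.
    """
    if min(N1_range) < 0 or min(N2_range) < 0:
        raise ValueError("ranges must be nonnegative")
    n1 = np.linspace(N1_range[0], N1_range[1], resolution)
    n2 = np.linspace(N2_range[0], N2_range[1], resolution)
    rows = []
    for x in n1:
        for y in n2:
            d = model.rhs(np.array([x, y]))
            rows.append((x, y, d[0], d[1]))
    return pd.DataFrame(rows, columns=["N1", "N2", "dN1_dt", "dN2_dt"])


def isocline_polylines(model: TwoSpeciesModel,
                       N1_range: tuple[float, float],
                       N2_range: tuple[float, float],
                       n_points: int = 100) -> pd.DataFrame:
    """Nontrivial zero-growth isoclines sampled as polylines.

    For species i the nontrivial isocline is the line
    ``r_i + a_i1 N1 + a_i2 N2 = 0``; a bounded model adds the ceiling lines
    ``N_i = Nmax``.  Returns a long-format table with columns
    ``isocline, N1, N2``.
    """
    frames = []
    x = np.linspace(N1_range[0], N1_range[1], n_points)
    if model.a12 != 0:
        y1 = -(model.r1 + model.a11 * x) / model.a12
    else:
        y1 = np.full_like(x, np.nan)  # vertical line N1 = -r1/a11
    frames.append(pd.DataFrame(
        {"isocline": "species1", "N1": x, "N2": y1}))
    if model.a21 != 0:
        # species-2 isocline expressed as N1(N2) may be steep; sample in N2
        y = np.linspace(N2_range[0], N2_range[1], n_points)
        x2 = -(model.r2 + model.a22 * y) / model.a21
        frames.append(pd.DataFrame(
            {"isocline": "species2", "N1": x2, "N2": y}))
    else:
        y = np.linspace(N2_range[0], N2_range[1], n_points)
        frames.append(pd.DataFrame(
            {"isocline": "species2",
             "N1": np.full_like(y, np.nan), "N2": y}))
    if model.bounded:
        y = np.linspace(N2_range[0], N2_range[1], n_points)
        frames.append(pd.DataFrame(
            {"isocline": "ceiling1", "N1": np.full_like(y, model.Nmax),
             "N2": y}))
        frames.append(pd.DataFrame(
            {"isocline": "ceiling2", "N1": x,
             "N2": np.full_like(x, model.Nmax)}))
    return pd.concat(frames, ignore_index=True)
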