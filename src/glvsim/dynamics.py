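"""Generalized Lotka-Volterra dynamics, original and bounded, with stopping rules.

Two variants of the community dynamics are integrated:

* the original GLV system ``dN_i/dt = N_i (r_i + sum_j a_ij N_j)``, in which
  populations may grow without limit, and
* the bounded model, in which each equation carries the attenuation factor
  ``(Nmax - N_i)/Nmax`` so that every abundance is capped at ``Nmax`` while
  any interior equilibrium of the original system is preserved.

A run stops for one of three reasons: *blow_up* (some population of the
unbounded model crosses the blow-up threshold; located by a root-finding
event so the stopping time is accurate), *converged* (``max_i |dN_i/dt|``
drops below the derivative tolerance, also event-located), or *time_limit*.
Survivors are the species whose final abundance strictly exceeds the
extinction threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .config import ScenarioConfig
from .errors import DimensionMismatchError, DomainError, IntegrationError
from .sampling import growth_rates_from_equilibrium, interaction_entries

__all__ = [
    "CommunityModel",
    "SimulationOutcome",
    "glv_rhs",
    "bounded_glv_rhs",
    "simulate",
    "classify_survivors",
    "NEGATIVE_FLOOR",
]

#: Tolerated numerical undershoot below zero.  Decaying populations settle at
#: magnitudes of order the solver's absolute tolerance, so the floor is set
#: well above atol yet far below any biologically meaningful abundance (and
#: below the 1e-4 extinction threshold).  Anything more negative is an error.
NEGATIVE_FLOOR = -1e-6


@dataclass(frozen=True)
class CommunityModel:
    """A parameterized GLV or bounded-GLV community.

    Holds the interaction matrix ``A``, the constructed interior equilibrium
    ``Nstar``, the intrinsic growth rates ``r`` (satisfying ``A N* + r = 0``),
    and, for the bounded variant, the abundance ceiling ``Nmax``.
    """

    A: np.ndarray
    Nstar: np.ndarray
    r: np.ndarray
    bounded: bool = False
    Nmax: Optional[float] = None

    def __post_init__(self) -> None:
        A = interaction_entries(self.A)
        object.__setattr__(self, "A", A)
        Nstar = np.asarray(self.Nstar, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "Nstar", Nstar)
        object.__setattr__(self, "r", r)
        S = A.shape[0]
        if Nstar.shape != (S,) or r.shape != (S,):
            raise DimensionMismatchError(
                f"A is {A.shape} but Nstar/r have shapes "
                f"{Nstar.shape}/{r.shape}")
        residual = np.abs(A @ Nstar + r).max()
        scale = max(1.0, np.abs(r).max())
        if residual > 1e-8 * scale:
            raise ValueError(
                f"Nstar is not an equilibrium: residual {residual:.3e}")
        if self.bounded:
            if self.Nmax is None or self.Nmax <= 0:
                raise ValueError("bounded model requires a positive Nmax")
            if self.Nmax <= Nstar.max():
                raise ValueError(
                    "Nmax must exceed every equilibrium abundance "
                    f"(Nmax={self.Nmax}, max N*={Nstar.max():.4g})")

    @classmethod
    def from_equilibrium(cls, A, Nstar, *, bounded: bool = False,
                         Nmax: Optional[float] = None) -> "CommunityModel":
        """Build the model whose growth rates make ``Nstar`` an equilibrium."""
        r = growth_rates_from_equilibrium(A, Nstar)
        return cls(A=interaction_entries(A), Nstar=np.asarray(Nstar, float),
                   r=r, bounded=bounded, Nmax=Nmax)

    @property
    def S(self) -> int:
        return self.A.shape[0]

    # -- right-hand sides and Jacobians used by the solver --------------------
    # These private versions skip domain checks and evaluate at the state
    # projected onto the admissible box [0, Nmax].  Adaptive solvers probe
    # slightly outside the box, where the raw vector field is anti-
    # dissipative: below zero a positive bracket drives the state to -inf,
    # and above the ceiling the attenuation factor flips sign with the same
    # effect.  The exact solution never leaves the box (0 and Nmax are
    # invariant), so the projection changes nothing inside it while pinning
    # rounding-level excursions instead of letting them run away.

    def _project(self, N: np.ndarray) -> np.ndarray:
        N = np.maximum(N, 0.0)
        if self.bounded:
            N = np.minimum(N, self.Nmax)
        return N

    def _rhs(self, N: np.ndarray) -> np.ndarray:
        N = self._project(N)
        growth = N * (self.r + self.A @ N)
        if self.bounded:
            growth *= (self.Nmax - N) / self.Nmax
        return growth

    def _jac(self, N: np.ndarray) -> np.ndarray:
        N = self._project(N)
        bracket = self.r + self.A @ N
        if not self.bounded:
            J = N[:, None] * self.A
            J[np.diag_indices_from(J)] += bracket
            return J
        phi = (self.Nmax - N) / self.Nmax
        J = (N * phi)[:, None] * self.A
        J[np.diag_indices_from(J)] += bracket * phi - N * bracket / self.Nmax
        return J


def glv_rhs(N: np.ndarray, model: CommunityModel) -> np.ndarray:
    """dN/dt of the original GLV system: N_i (r_i + sum_j a_ij N_j)."""
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise DomainError("abundances must be nonnegative")
    return N * (model.r + model.A @ N)


def bounded_glv_rhs(N: np.ndarray, model: CommunityModel) -> np.ndarray:
    """dN/dt of the bounded model: the GLV rate times (Nmax - N_i)/Nmax."""
    if not model.bounded:
        raise ValueError("model is not bounded; use glv_rhs")
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise DomainError("abundances must be nonnegative")
    if np.any(N > model.Nmax):
        raise DomainError(f"abundances must not exceed Nmax={model.Nmax}")
    return N * (model.r + model.A @ N) * (model.Nmax - N) / model.Nmax


def classify_survivors(N_final: np.ndarray,
                       extinction_threshold: float) -> np.ndarray:
    """Alive mask: strictly greater than the extinction threshold.

    A final abundance exactly at the threshold counts as extinct.
    """
    return np.asarray(N_final, dtype=float) > extinction_threshold


@dataclass(frozen=True)
class SimulationOutcome:
    """Terminal state and classification of one simulated trajectory."""

    stop_reason: str                 # "converged" | "blow_up" | "time_limit"
    t_stop: float
    N_final: np.ndarray
    alive_mask: np.ndarray
    n_alive: int
    n_at_ceiling: int
    returned_to_Nstar: bool
    trajectory: Optional[tuple[np.ndarray, np.ndarray]] = field(default=None,
                                                                repr=False)


def _clamp_nonnegative(N: np.ndarray) -> np.ndarray:
    """Zero out tiny negative solver excursions; large ones are errors."""
    if N.min() < NEGATIVE_FLOOR:
        raise IntegrationError(
            f"solver produced abundance {N.min():.3e} below the tolerated "
            f"floor {NEGATIVE_FLOOR:.0e}")
    return np.where(N < 0.0, 0.0, N)


def simulate(model: CommunityModel, N0: np.ndarray, config: ScenarioConfig,
             record_trajectory: bool = False) -> SimulationOutcome:
    """Integrate a community from a perturbed state until a stopping rule fires.

    Uses LSODA (adaptive, stiffness-switching) with the analytic Jacobian.
    Stopping rules, in the order they can fire:

    * ``blow_up`` - unbounded model only: any abundance crosses
      ``config.blow_up_threshold`` from below (terminal root-located event);
    * ``converged`` - ``max_i |dN_i/dt|`` falls below
      ``config.derivative_tol`` (terminal root-located event);
    * ``time_limit`` - the integration reaches ``config.t_max``.

    The returned-to-equilibrium flag is true when the run converged and the
    final state lies within ``10 * perturb_sd`` (sup-norm) of ``Nstar``.
    """
    y0 = np.asarray(N0, dtype=float)
    if y0.shape != (model.S,):
        raise DimensionMismatchError(
            f"initial state of shape {y0.shape} does not match S={model.S}")
    if np.any(y0 < 0):
        raise DomainError("initial abundances must be nonnegative")
    if model.bounded and np.any(y0 > model.Nmax):
        raise DomainError("initial abundances must not exceed Nmax")

    def fun(t, y):
        return model._rhs(y)

    def jac(t, y):
        return model._jac(y)

    def convergence_event(t, y):
        return np.abs(model._rhs(y)).max() - config.derivative_tol

    convergence_event.terminal = True
    convergence_event.direction = -1

    events: list[Callable] = [convergence_event]
    if not model.bounded:
        # The bounded model approaches Nmax >= blow_up_threshold only
        # asymptotically, so the blow-up rule applies to the original model.
        def blow_up_event(t, y):
            return y.max() - config.blow_up_threshold

        blow_up_event.terminal = True
        blow_up_event.direction = 1
        events.append(blow_up_event)

    # Already at (numerical) rest: nothing to integrate.
    if convergence_event(0.0, y0) < 0:
        return _build_outcome(model, config, "converged", 0.0, y0.copy(),
                              trajectory=(np.array([0.0]), y0[None, :].copy())
                              if record_trajectory else None)

    t_eval = None
    if record_trajectory:
        t_eval = np.arange(0.0, config.t_max + 0.5 * config.checkpoint_dt,
                           config.checkpoint_dt)

    sol = solve_ivp(fun, (0.0, config.t_max), y0, method="LSODA", jac=jac,
                    rtol=config.rtol, atol=config.atol, events=events,
                    t_eval=t_eval, dense_output=False)
    if sol.status == -1:
        raise IntegrationError(f"LSODA failed: {sol.message}",
                               t=sol.t, y=sol.y)

    if sol.status == 1:  # a terminal event fired
        if len(events) > 1 and sol.t_events[1].size:
            stop_reason = "blow_up"
            t_stop = float(sol.t_events[1][0])
            N_final = sol.y_events[1][0]
        else:
            stop_reason = "converged"
            t_stop = float(sol.t_events[0][0])
            N_final = sol.y_events[0][0]
    else:
        stop_reason = "time_limit"
        t_stop = float(config.t_max)
        N_final = sol.y[:, -1] if sol.y.size else y0

    trajectory = None
    if record_trajectory:
        t_out, y_out = sol.t, sol.y.T
        if t_out.size == 0 or t_out[-1] < t_stop:
            t_out = np.append(t_out, t_stop)
            y_out = np.vstack([y_out, N_final]) if y_out.size else N_final[None, :]
        y_out = np.maximum(y_out, 0.0)
        if model.bounded:
            y_out = np.minimum(y_out, model.Nmax)
        trajectory = (t_out, y_out)

    return _build_outcome(model, config, stop_reason, t_stop,
                          np.array(N_final, dtype=float), trajectory)


def _build_outcome(model: CommunityModel, config: ScenarioConfig,
                   stop_reason: str, t_stop: float, N_final: np.ndarray,
                   trajectory) -> SimulationOutcome:
    N_final = _clamp_nonnegative(N_final)
    if model.bounded:
        N_final = np.minimum(N_final, model.Nmax)
    alive_mask = classify_survivors(N_final, config.extinction_threshold)
    n_at_ceiling = 0
    if model.bounded:
        # the ceiling is approached only asymptotically; 0.1% is "reached"
        n_at_ceiling = int(np.count_nonzero(N_final >= 0.999 * model.Nmax))
    return_tol = 10.0 * config.perturb_sd if config.perturb_sd > 0 else 1e-8
    returned = bool(stop_reason == "converged"
                    and np.abs(N_final - model.Nstar).max() < return_tol)
    return SimulationOutcome(
        stop_reason=stop_reason,
        t_stop=t_stop,
        N_final=N_final,
        alive_mask=alive_mask,
        n_alive=int(alive_mask.sum()),
        n_at_ceiling=n_at_ceiling,
        returned_to_Nstar=returned,
        trajectory=trajectory,
    )
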