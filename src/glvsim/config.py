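"""Scenario configuration for random-community Lotka-Volterra experiments.

A :class:`ScenarioConfig` bundles everything needed to reproduce one
experimental condition: the community-sampling parameters (richness ``S``,
connectance ``c``, interaction-strength scale ``sigma``, sign constraint),
the dynamical variant (original vs. bounded model, ceiling ``Nmax``), the
stopping thresholds, and the replication plan (``n_reps``, root ``seed``).
Configs are immutable; derived variants are made with
:func:`dataclasses.replace` or :meth:`ScenarioConfig.with_overrides`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

SIGN_MODES = ("mixed", "all_negative", "all_positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one random-community scenario.

    Parameters
    ----------
    S
        Initial species richness (>= 2).
    c
        Connectance: the proportion of off-diagonal interaction coefficients
        that are nonzero. The realized count is exactly ``round(c*S*(S-1))``.
    sigma
        Standard deviation of the Gaussian from which nonzero interspecific
        coefficients are drawn (per-capita rate per unit abundance).
    sign_mode
        ``"mixed"`` leaves the Gaussian draws untouched; ``"all_negative"`` /
        ``"all_positive"`` force every interspecific coefficient to the given
        sign (half-Gaussian magnitudes). The diagonal is always -1.
    bounded
        If True, simulate the bounded model in which each per-capita growth
        rate carries the attenuation factor ``(Nmax - N_i)/Nmax``.
    Nmax
        Abundance ceiling of the bounded model.
    perturb_sd
        SD of the additive Gaussian perturbation applied to the equilibrium
        to build initial conditions.
    blow_up_threshold
        Abundance at which a population of the *unbounded* model is declared
        to be on its way to infinity and the run is stopped.
    extinction_threshold
        Final abundance strictly above which a species counts as alive.
    derivative_tol
        Convergence criterion: the run has converged once
        ``max_i |dN_i/dt|`` falls below this value.
    t_max
        Time horizon; runs still going at ``t_max`` stop with ``time_limit``.
    n_reps
        Number of independent replicate communities per condition.
    seed
        Root seed; per-replicate streams are derived deterministically from
        ``(seed, S, replicate_id)`` so results do not depend on run order.
    rtol, atol
        Relative/absolute tolerances handed to the ODE solver.
    checkpoint_dt
        Spacing of trajectory output points when a trajectory is recorded.
    near_total_fraction
        A final community with ``n_alive <= near_total_fraction * S`` counts
        as a near-total extinction in outcome classification.
    """

    S: int = 10
    c: float = 0.7
    sigma: float = 0.2
    sign_mode: str = "mixed"
    bounded: bool = False
    Nmax: float = 1000.0
    perturb_sd: float = 0.02
    blow_up_threshold: float = 1000.0
    extinction_threshold: float = 1e-4
    derivative_tol: float = 1e-5
    t_max: float = 1000.0
    n_reps: int = 1000
    seed: int = 0
    rtol: float = 1e-8
    atol: float = 1e-10
    checkpoint_dt: float = 1.0
    near_total_fraction: float = 0.1

    def __post_init__(self) -> None:
        if int(self.S) != self.S or self.S < 2:
            raise ValueError(f"S must be an integer >= 2, got {self.S}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"connectance c must lie in [0, 1], got {self.c}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.sign_mode not in SIGN_MODES:
            raise ValueError(
                f"sign_mode must be one of {SIGN_MODES}, got {self.sign_mode!r}")
        if self.perturb_sd < 0:
            raise ValueError("perturb_sd must be >= 0")
        if not (self.extinction_threshold < 1.0 < self.blow_up_threshold):
            raise ValueError(
                "thresholds must satisfy extinction_threshold < 1 < blow_up_threshold")
        if self.blow_up_threshold > self.Nmax:
            raise ValueError("blow_up_threshold must not exceed Nmax")
        if self.derivative_tol <= 0 or self.t_max <= 0:
            raise ValueError("derivative_tol and t_max must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.rtol <= 0 or self.atol <= 0 or self.checkpoint_dt <= 0:
            raise ValueError("solver settings must be positive")
        if not 0.0 <= self.near_total_fraction <= 1.0:
            raise ValueError("near_total_fraction must lie in [0, 1]")

    # -- construction helpers -------------------------------------------------

    def with_overrides(self, **overrides: Any) -> "ScenarioConfig":
        """Return a copy with the given fields replaced (None values ignored)."""
        clean = {k: v for k, v in overrides.items() if v is not None}
        unknown = set(clean) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return dataclasses.replace(self, **clean)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ScenarioConfig":
        return cls().with_overrides(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a flat key/value YAML config file (keys = field names)."""
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
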