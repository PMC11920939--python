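"""Replicated random-community experiments and figure-level summaries.

One *replicate* is the full pipeline: sample an interaction matrix and an
equilibrium, build the community model, test local stability from the
Jacobian spectrum, perturb the equilibrium, integrate the (original or
bounded) dynamics to a stopping rule, and classify the outcome.  A *richness
sweep* repeats this ``n_reps`` times at each richness on a grid and
aggregates per-richness summaries: proportion locally stable, proportion
blowing up, mean number of survivors, and the interaction-selection
statistic (the shift in mean realized interaction strength between the
surviving subcommunity and the initial pool).

Replicate random streams are derived from ``(root seed, S, replicate_id)``,
so any replicate can be reproduced in isolation and results are invariant
to execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .dynamics import CommunityModel, simulate
from .errors import UndefinedStatisticError
from .sampling import (interaction_entries, perturb, sample_equilibrium,
                       sample_interaction_matrix)
from .stability import is_locally_stable, jacobian_at_equilibrium

__all__ = [
    "ReplicateRecord",
    "SweepResult",
    "replicate_rng",
    "run_replicate",
    "run_richness_sweep",
    "summarize_records",
    "interaction_selection_statistic",
    "classify_positive_scenario_outcome",
    "collect_unstable_replicates",
    "DEFAULT_S_GRID",
]

#: Default richness grid: 10 to 250 species in increments of 10.
DEFAULT_S_GRID: tuple[int, ...] = tuple(range(10, 251, 10))


@dataclass(frozen=True)
class ReplicateRecord:
    """Per-replicate outcome of one random community."""

    S: int
    replicate_id: int
    seed: int
    is_stable: bool
    is_marginal: bool
    max_real_part: float
    stop_reason: str
    t_stop: float
    n_alive: int
    n_at_ceiling: int
    blow_up: bool
    all_alive: bool
    returned_to_Nstar: bool
    delta_mean_interaction: float  # NaN when undefined


@dataclass(frozen=True)
class SweepResult:
    """All replicate records of a sweep plus per-richness summaries."""

    records: list[ReplicateRecord]
    summary: pd.DataFrame = field(repr=False)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def replicate_rng(seed: int, S: int, replicate_id: int) -> np.random.Generator:
    """Deterministic per-replicate random stream, independent of run order."""
    return np.random.default_rng(np.random.SeedSequence([seed, S, replicate_id]))


def interaction_selection_statistic(A, alive_mask: np.ndarray) -> float:
    """Shift in mean realized interaction strength after community collapse.

    Returns the mean of the nonzero off-diagonal coefficients restricted to
    the surviving species minus the same mean over the full initial matrix.
    Zero when every species survives; positive when the surviving
    subcommunity is enriched in positive interactions.

    Raises :class:`UndefinedStatisticError` for fewer than two survivors;
    returns NaN when the survivor submatrix carries no realized interaction.
    """
    entries = interaction_entries(A)
    alive_mask = np.asarray(alive_mask, dtype=bool)
    survivors = np.flatnonzero(alive_mask)
    if survivors.size < 2:
        raise UndefinedStatisticError(
            f"selection statistic needs >= 2 survivors, got {survivors.size}")

    def _mean_links(M: np.ndarray) -> float:
        off = ~np.eye(M.shape[0], dtype=bool)
        vals = M[off]
        vals = vals[vals != 0.0]
        return float(vals.mean()) if vals.size else np.nan

    sub = entries[np.ix_(survivors, survivors)]
    sub_mean = _mean_links(sub)
    full_mean = _mean_links(entries)
    if np.isnan(sub_mean) or np.isnan(full_mean):
        return float("nan")
    return sub_mean - full_mean


def run_replicate(config: ScenarioConfig, replicate_id: int) -> ReplicateRecord:
    """Sample, stability-test, perturb and simulate one random community."""
    rng = replicate_rng(config.seed, config.S, replicate_id)
    A = sample_interaction_matrix(config, rng)
    Nstar = sample_equilibrium(config.S, rng)
    model = CommunityModel.from_equilibrium(
        A, Nstar, bounded=config.bounded,
        Nmax=config.Nmax if config.bounded else None)
    report = is_locally_stable(jacobian_at_equilibrium(A, Nstar))
    N0 = perturb(Nstar, config.perturb_sd, rng)
    outcome = simulate(model, N0, config)
    try:
        delta = interaction_selection_statistic(A, outcome.alive_mask)
    except UndefinedStatisticError:
        delta = float("nan")
    return ReplicateRecord(
        S=config.S,
        replicate_id=replicate_id,
        seed=config.seed,
        is_stable=report.is_stable,
        is_marginal=report.is_marginal,
        max_real_part=report.max_real_part,
        stop_reason=outcome.stop_reason,
        t_stop=outcome.t_stop,
        n_alive=outcome.n_alive,
        n_at_ceiling=outcome.n_at_ceiling,
        blow_up=outcome.stop_reason == "blow_up",
        all_alive=outcome.n_alive == config.S,
        returned_to_Nstar=outcome.returned_to_Nstar,
        delta_mean_interaction=delta,
    )


def summarize_records(records: Iterable[ReplicateRecord],
                      near_total_fraction: float = 0.1) -> pd.DataFrame:
    """Aggregate replicate records into one summary row per richness."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if df.empty:
        raise ValueError("no records to summarize")

    rows = []
    for S, group in df.groupby("S", sort=True):
        rows.append({
            "S": int(S),
            "n_reps": len(group),
            "prop_stable": group["is_stable"].mean(),
            "prop_blow_up": group["blow_up"].mean(),
            "mean_n_alive": group["n_alive"].mean(),
            "mean_n_at_ceiling": group["n_at_ceiling"].mean(),
            "prop_no_extinction": group["all_alive"].mean(),
            "prop_all_extinct_or_nearly":
                (group["n_alive"] <= near_total_fraction * int(S)).mean(),
            "mean_delta_interaction": group["delta_mean_interaction"].mean(),
        })
    return pd.DataFrame(rows)


def run_richness_sweep(base_config: ScenarioConfig,
                       S_grid: Optional[Sequence[int]] = None,
                       n_reps: Optional[int] = None,
                       progress: Optional[callable] = None) -> SweepResult:
    """Run ``n_reps`` replicates at every richness of the grid.

    The default grid spans 10..250 in steps of 10 with 1000 replicates per
    richness; scaled-down grids and replicate counts are first-class.
    ``progress``, if given, is called as ``progress(S, records_for_S)`` after
    each richness completes.
    """
    grid = tuple(DEFAULT_S_GRID if S_grid is None else S_grid)
    if not grid:
        raise ValueError("S_grid must be nonempty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("S_grid must be strictly ascending")
    reps = base_config.n_reps if n_reps is None else int(n_reps)

    records: list[ReplicateRecord] = []
    for S in grid:
        config = base_config.with_overrides(S=int(S), n_reps=reps)
        batch = [run_replicate(config, rep) for rep in range(reps)]
        records.extend(batch)
        if progress is not None:
            progress(S, batch)
    summary = summarize_records(records, base_config.near_total_fraction)
    return SweepResult(records=records, summary=summary)


def classify_positive_scenario_outcome(record: ReplicateRecord,
                                       near_total_fraction: float = 0.1) -> str:
    """Classify an all-positive bounded run: all alive, near-total extinction, other.

    ``all_alive`` when every species persists; ``near_total_extinction`` when
    at most ``near_total_fraction * S`` do; ``other`` in between.
    """
    if record.n_alive == record.S:
        return "all_alive"
    if record.n_alive <= near_total_fraction * record.S:
        return "near_total_extinction"
    return "other"


def collect_unstable_replicates(config: ScenarioConfig, n: int,
                                max_tries: Optional[int] = None
                                ) -> list[ReplicateRecord]:
    """First ``n`` replicates whose initial equilibrium is locally unstable.

    Replicate ids are scanned in order from 0; stable (or marginal) draws are
    discarded.  Raises if ``max_tries`` (default ``20 * n``) ids are exhausted
    first.
    """
    limit = 20 * n if max_tries is None else max_tries
    kept: list[ReplicateRecord] = []
    for replicate_id in range(limit):
        record = run_replicate(config, replicate_id)
        if not record.is_stable and not record.is_marginal:
            kept.append(record)
            if len(kept) == n:
                return kept
    raise RuntimeError(
        f"only {len(kept)}/{n} unstable replicates found in {limit} tries")
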