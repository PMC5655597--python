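"""Batch execution of the simulation design.

Simulees sit on a grid of trait values: for each grid value ``g`` the true
trait vector has every coordinate equal to ``g``, replicated
``replicates_per_point`` times (defaults: 21 points from -2 to +2 in steps
of 0.2, 1000 replicates — 21,000 simulees).

Each simulee gets an independent random substream derived from the master
seed and its (grid point, replicate) index, so serial and parallel
execution produce identical results and any single test can be re-run in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .engine import CATConfig, CATResult, run_cat
from .mgrm import ItemBank

__all__ = ["StudyDesign", "generate_theta_grid", "run_study", "respondent_rng"]


@dataclass(frozen=True)
class StudyDesign:
    """Grid of true trait values and replication counts."""

    grid_lo: float = -2.0
    grid_hi: float = 2.0
    grid_step: float = 0.2
    replicates_per_point: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_point < 1:
            raise ValueError("replicates_per_point must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        n = (self.grid_hi - self.grid_lo) / self.grid_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid_step {self.grid_step} does not divide the range "
                f"[{self.grid_lo}, {self.grid_hi}]"
            )

    @property
    def grid_values(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step))
        return np.round(self.grid_lo + self.grid_step * np.arange(n + 1), 10)


def generate_theta_grid(
    design: StudyDesign, n_dimensions: int
) -> list[tuple[float, np.ndarray]]:
    """All simulee trait vectors: every coordinate equals the grid value."""
    out = []
    for g in design.grid_values:
        vec = np.full(n_dimensions, g)
        out.extend((float(g), vec.copy()) for _ in range(design.replicates_per_point))
    return out


def respondent_rng(master_seed: int, grid_index: int, replicate: int) -> np.random.Generator:
    """Independent substream for one simulee, re-derivable in isolation."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(grid_index, replicate))
    )


def _run_one(
    bank: ItemBank,
    config: CATConfig,
    master_seed: int,
    gi: int,
    g: float,
    rep: int,
    n_dimensions: int,
) -> CATResult:
    rng = respondent_rng(master_seed, gi, rep)
    result = run_cat(
        bank,
        np.full(n_dimensions, g),
        config,
        rng=rng,
        respondent_id=f"g{gi}_r{rep}",
    )
    result.grid_value = g
    return result


def run_study(
    bank: ItemBank,
    design: StudyDesign,
    config: CATConfig,
    n_jobs: int = 1,
    progress: Callable[[Iterable], Iterable] | None = None,
) -> list[CATResult]:
    """Run one adaptive test per simulee of the design.

    ``n_jobs > 1`` parallelises over simulees with joblib if available;
    seeding guarantees output identical to the serial run.  ``progress``
    may wrap the task iterable (e.g. ``tqdm``).
    """
    D = bank.n_dimensions
    tasks = [
        (gi, float(g), rep)
        for gi, g in enumerate(design.grid_values)
        for rep in range(design.replicates_per_point)
    ]
    if progress is not None:
        tasks = progress(tasks)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=n_jobs)(
            delayed(_run_one)(bank, config, design.seed, gi, g, rep, D)
            for gi, g, rep in tasks
        )
    return [_run_one(bank, config, design.seed, gi, g, rep, D) for gi, g, rep in tasks]
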