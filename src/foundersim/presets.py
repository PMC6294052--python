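"""Experiment presets mirroring the published result panels at desk scale.

Each preset bundles a parameter grid, a base parameter set and a replicate
count.  Desk-scale defaults use 10 replicates (and 1,000 generations for the
long time-course panels); ``full=True`` restores the full replicate counts
(50, or 100 for the selection/recombination sweep) and generation spans.

The migration grid of ``fig2`` is a reconstruction: the source panel does
not enumerate its M ticks, so the grid spans the documented 0–1e5 migrant
range on a log-ish ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Mapping

import pandas as pd

from .engine import SimulationParams, run_experiment

__all__ = ["ExperimentPreset", "preset", "available_presets"]

_K_LADDER = [2e2, 2e3, 2e4, 2e5, 2e6, 2e7]


@dataclass(frozen=True)
class ExperimentPreset:
    """A named parameter grid with replicate counts and snapshot schedule."""

    name: str
    description: str
    grid: Mapping[str, tuple]
    base: SimulationParams
    replicates: int = 10
    full_replicates: int = 50
    full_Y: int | None = None
    snapshot_every: int = 1

    @property
    def n_combinations(self) -> int:
        size = 1
        for vals in self.grid.values():
            size *= len(vals)
        return size

    def run(self, seed: int | None = None, full: bool = False,
            replicates: int | None = None,
            snapshot_every: int | None = None) -> pd.DataFrame:
        """Execute the preset and return the tidy results table."""
        reps = replicates if replicates is not None else (
            self.full_replicates if full else self.replicates)
        base = self.base
        if full and self.full_Y is not None:
            base = replace(base, Y=self.full_Y)
        return run_experiment(
            dict(self.grid), replicates=reps, seed=seed, base=base,
            snapshot_every=snapshot_every if snapshot_every is not None
            else self.snapshot_every,
            preset_name=self.name)


def _neutral_base(**kw: Any) -> SimulationParams:
    return SimulationParams(**{"F": 1, "M": 2, "Y": 1000, "r": 0.3,
                               "n": 5, "s": 0, **kw})


_PRESETS: dict[str, ExperimentPreset] = {}


def _register(p: ExperimentPreset) -> None:
    _PRESETS[p.name] = p


_register(ExperimentPreset(
    name="fig2",
    description="FST after 1,000 generations against migration M, "
                "for small and large K, with and without an egg bank",
    grid={"M": (0, 1, 2, 10, 100, 1_000, 10_000, 100_000),
          "K": (2e2, 2e7),
          "bank_present": (True, False)},
    base=_neutral_base(),
))

_register(ExperimentPreset(
    name="fig3",
    description="FST after 1,000 generations against carrying capacity K, "
                "with and without an egg bank (M = 2)",
    grid={"K": tuple(_K_LADDER), "bank_present": (True, False)},
    base=_neutral_base(),
))

_register(ExperimentPreset(
    name="fig4",
    description="FST time course and Delta-FST across K "
                "(long-run trajectories)",
    grid={"K": tuple(_K_LADDER), "bank_present": (True, False)},
    base=_neutral_base(),
    full_Y=4000,
    snapshot_every=10,
))

_register(ExperimentPreset(
    name="fig5",
    description="FST after 1,000 generations over growth-rate x carrying-"
                "capacity combinations",
    grid={"r": (0.05, 0.1, 0.2, 0.3, 0.5, 1.0),
          "K": tuple(_K_LADDER),
          "bank_present": (True, False)},
    base=_neutral_base(),
))

_register(ExperimentPreset(
    name="fig6",
    description="FST time course for founder numbers F = 1, 2, 5, 50 at "
                "two carrying capacities",
    grid={"F": (1, 2, 5, 50), "K": (2e4, 2e7),
          "bank_present": (True, False)},
    base=_neutral_base(),
    full_Y=4000,
    snapshot_every=10,
))

_register(ExperimentPreset(
    name="fig7",
    description="FST and FSTQ after 1,000 generations across recombination "
                "rates under weak and strong selection (egg bank present)",
    grid={"c": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
          "delta": (1e-4, 1e-2),
          "K": (2e4, 2e7)},
    base=_neutral_base(s=5, bank_present=True),
    full_replicates=100,
))


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> ExperimentPreset:
    """Look up a preset by name; unknown names list the available ones."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        ) from None
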