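"""Scenario orchestration: founding, the yearly loop, replicates, sweeps.

Two localities are founded simultaneously by ``F`` diapausing eggs drawn
from a single infinite Hardy–Weinberg source population whose per-locus
allele frequencies are themselves drawn uniformly anew for every replicate.
Each subsequent sexual generation runs the demographic cycle

    hatching -> clonal growth to tau -> egg production -> bank survival
    -> reciprocal egg migration

with FST/FSTQ recorded just after hatching, so the generation-1 record
already reflects the first migrants.  Founding eggs hatch immediately and
fully: establishment from a single egg is taken as given, rather than
being subjected to the annual hatching fraction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import demography, stats
from ._state import StateSpace, get_space
from .demography import DemographyParams

__all__ = [
    "SimulationParams",
    "SourcePopulation",
    "LocalityState",
    "ReplicateResult",
    "found_populations",
    "run_generation",
    "run_replicate",
    "run_experiment",
]


@dataclass(frozen=True)
class SimulationParams:
    """Full parameter set of one simulation scenario.

    Defaults are the baseline rotifer-like values: a 60-day growth season,
    basal clonal growth rate 0.3 d^-1, sexual proportion 0.7, sex ratio 0.5,
    three diapausing eggs per sexual female, bank survival 0.763 and
    hatching fraction 0.046 per year, five neutral loci, a single founding
    egg and no selection.
    """

    F: int = 1                # founders (diapausing eggs)
    M: int = 2                # migrant eggs per sexual generation, each way
    Y: int = 1000             # sexual generations
    tau: float = 60.0         # growth-season length (days)
    r: float = 0.3            # basal clonal growth rate (days^-1)
    K: float = 2e7            # carrying capacity (individuals)
    m: float = 0.7            # sexual proportion
    sr: float = 0.5           # sex ratio
    e: float = 3.0            # diapausing eggs per sexual female
    n: int = 5                # neutral loci (= locus pairs)
    s: int = 0                # selected loci: 0 or n
    delta: float = 0.0        # additive fitness effect on r (days^-1)
    c: float = 0.5            # within-pair recombination fraction
    gamma: float = 0.763      # annual egg-bank survival
    lam: float = 0.046        # annual hatching fraction
    bank_present: bool = True
    replicates: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.F < 1:
            raise ValueError("F must be at least 1")
        if self.M < 0:
            raise ValueError("M must be non-negative")
        if self.Y < 1:
            raise ValueError("Y must be at least 1")
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.s not in (0, self.n):
            raise ValueError("s must be 0 or equal to n")
        if not 0.0 <= self.c <= 0.5:
            raise ValueError(f"recombination rate must be in [0, 0.5], got {self.c}")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")
        # delegate range checks on the demographic block
        self.demography()

    @property
    def has_selection(self) -> bool:
        return self.s > 0

    def demography(self) -> DemographyParams:
        return DemographyParams(r=self.r, K=self.K, tau=self.tau, m=self.m,
                                sr=self.sr, e=self.e, gamma=self.gamma,
                                lam=self.lam, bank_present=self.bank_present)

    def space(self) -> StateSpace:
        return get_space(self.n, self.has_selection)


@dataclass(frozen=True)
class SourcePopulation:
    """Infinite HWE source: per-locus allele-1 frequencies, loci unlinked.

    All loci — selected ones included — are neutral in the source, so no
    preadaptation to either locality exists.  Sampling founders or migrants
    never alters the frequencies.
    """

    neutral_freqs: np.ndarray
    sel_freqs: np.ndarray | None = None

    @classmethod
    def random(cls, n: int, selected: bool,
               rng: np.random.Generator) -> "SourcePopulation":
        """Frequencies drawn uniformly on (0, 1), one set per replicate."""
        neutral = rng.uniform(0.0, 1.0, size=n)
        sel = rng.uniform(0.0, 1.0, size=n) if selected else None
        return cls(neutral_freqs=neutral, sel_freqs=sel)


@dataclass
class LocalityState:
    """Mutable per-locality state: plankton densities and egg-bank counts."""

    plankton: np.ndarray
    bank: np.ndarray

    @property
    def extinct(self) -> bool:
        return self.plankton.sum() <= 0 and self.bank.sum() <= 0


@dataclass
class ReplicateResult:
    """Trajectory of one replicate: one FstRecord per sexual generation.

    ``extinct_at`` is the generation at which a locality lost both its
    plankton and its bank (trajectory truncated there), or None.
    """

    records: list[stats.FstRecord]
    states: tuple[LocalityState, LocalityState]
    source: SourcePopulation
    seed: int | None
    extinct_at: int | None = None

    @property
    def extinct(self) -> bool:
        return self.extinct_at is not None

    def trajectory(self, attr: str = "fst") -> np.ndarray:
        return np.array([getattr(rec, attr) for rec in self.records])


def found_populations(source: SourcePopulation, F: int,
                      rng: np.random.Generator,
                      space: StateSpace) -> tuple[LocalityState, LocalityState]:
    """Found both localities with ``F`` eggs each, drawn from the source.

    Founder genotypes are independent HWE draws with haplotypes at linkage
    equilibrium.  Founding eggs hatch immediately and fully, entering the
    plankton; banks start empty.
    """
    if F < 1:
        raise ValueError("F must be at least 1")
    states = []
    for _ in range(2):
        counts = space.sample_hwe(source.neutral_freqs, source.sel_freqs,
                                  F, rng)
        states.append(LocalityState(plankton=counts,
                                    bank=np.zeros(space.n_genotypes)))
    return states[0], states[1]


def _record_after_hatching(states: Sequence[LocalityState], y: int,
                           space: StateSpace) -> stats.FstRecord:
    """FST/FSTQ snapshot from the hatchling censuses of both localities."""
    c1 = float(states[0].plankton.sum())
    c2 = float(states[1].plankton.sum())
    fst_v = fstq_v = h_t = h_s = math.nan
    if c1 > 0 and c2 > 0:
        pn1, ps1 = space.allele_freqs(states[0].plankton)
        pn2, ps2 = space.allele_freqs(states[1].plankton)
        fst_v, h_t, h_s = stats.fst_from_frequencies(pn1, pn2, c1, c2)
        if space.selected:
            fstq_v, _, _ = stats.fst_from_frequencies(ps1, ps2, c1, c2)
    return stats.FstRecord(y=y, fst=fst_v, fstq=fstq_v, h_t=h_t, h_s=h_s,
                           census_1=c1, census_2=c2)


def _run_season(states: Sequence[LocalityState], params: SimulationParams,
                space: StateSpace, rng: np.random.Generator,
                rates: Sequence[np.ndarray]) -> tuple[float, float]:
    """Grow to tau, produce eggs, age the banks, exchange migrants.

    Returns the end-of-season plankton totals.  Migration is synchronous:
    both draws use the donors' post-survival, pre-exchange banks.
    """
    demo = params.demography()
    totals = []
    for loc, state in enumerate(states):
        grown = demography.asexual_growth(state.plankton, rates[loc],
                                          params.K, params.tau)
        totals.append(float(grown.sum()))
        cohort = demography.produce_eggs(grown, demo, space, params.c, rng)
        state.plankton = grown
        state.bank = demography.bank_survive(state.bank + cohort, demo, rng)
    if params.M > 0:
        inbound = [demography.migrate(states[1].bank, params.M, rng),
                   demography.migrate(states[0].bank, params.M, rng)]
        for state, eggs in zip(states, inbound):
            state.bank = state.bank + eggs
    return totals[0], totals[1]


def run_generation(states: Sequence[LocalityState], params: SimulationParams,
                   space: StateSpace, rng: np.random.Generator,
                   y: int, rates: Sequence[np.ndarray] | None = None
                   ) -> stats.FstRecord:
    """Advance both localities through sexual generation ``y``.

    Hatches the post-migration banks, records FST/FSTQ from the hatchling
    censuses, then runs the season (growth, egg production, bank survival,
    reciprocal migration).  The record's ``density_tau_*`` fields hold the
    end-of-season totals of the same generation.
    """
    demo = params.demography()
    if rates is None:
        rates = [space.growth_rates(params.r, params.delta, loc)
                 for loc in (1, 2)]
    for state in states:
        hatched, remaining = demography.bank_hatch(state.bank, demo, rng)
        state.plankton = hatched
        state.bank = remaining
    rec = _record_after_hatching(states, y, space)
    d1, d2 = _run_season(states, params, space, rng, rates)
    return replace(rec, density_tau_1=d1, density_tau_2=d2)


def run_replicate(params: SimulationParams,
                  replicate_seed: int | None = None) -> ReplicateResult:
    """Simulate one replicate: fresh source, foundation, Y generations.

    Deterministic given ``replicate_seed`` (falls back to ``params.seed``).
    A replicate ends early if a locality loses both plankton and bank; the
    truncated trajectory is flagged via ``extinct_at``.
    """
    seed = params.seed if replicate_seed is None else replicate_seed
    rng = np.random.default_rng(seed)
    space = params.space()
    source = SourcePopulation.random(params.n, params.has_selection, rng)
    s1, s2 = found_populations(source, params.F, rng, space)
    states = (s1, s2)
    rates = [space.growth_rates(params.r, params.delta, loc)
             for loc in (1, 2)]
    # founding year: founders are already hatched; run the season directly
    _run_season(states, params, space, rng, rates)
    records: list[stats.FstRecord] = []
    extinct_at = None
    for y in range(1, params.Y + 1):
        records.append(run_generation(states, params, space, rng, y, rates))
        if any(state.extinct for state in states):
            extinct_at = y
            break
    return ReplicateResult(records=records, states=states, source=source,
                           seed=seed, extinct_at=extinct_at)


def _spawn_seeds(master_seed: int | None, count: int) -> np.ndarray:
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=count)


def run_experiment(param_grid: Mapping[str, Iterable] | Sequence[Mapping],
                   replicates: int, seed: int | None = None,
                   base: SimulationParams | None = None,
                   snapshot_every: int = 1,
                   preset_name: str = "") -> pd.DataFrame:
    """Cross a parameter grid with replicates; return a tidy results table.

    ``param_grid`` is either a mapping of SimulationParams field names to
    value lists (full cross product) or an explicit sequence of override
    dicts.  Each (combination, replicate) gets an independent integer seed
    spawned from ``seed``, so rows are reproducible and independent of
    execution order.  One row is emitted per recorded generation, thinned to
    every ``snapshot_every``-th generation (the first and last are always
    kept).
    """
    base = base if base is not None else SimulationParams()
    if isinstance(param_grid, Mapping):
        keys = list(param_grid.keys())
        combos = [dict(zip(keys, vals))
                  for vals in itertools.product(*param_grid.values())]
    else:
        combos = [dict(d) for d in param_grid]
    if not combos:
        raise ValueError("parameter grid is empty")
    seeds = _spawn_seeds(seed, len(combos) * replicates)
    rows = []
    k = 0
    for combo in combos:
        params = replace(base, **combo)
        for rep in range(replicates):
            rep_seed = int(seeds[k]); k += 1
            result = run_replicate(params, rep_seed)
            last_y = result.records[-1].y if result.records else 0
            for rec in result.records:
                if rec.y % snapshot_every and rec.y not in (1, last_y):
                    continue
                rows.append({
                    "preset": preset_name, "replicate": rep,
                    "seed": rep_seed, "y": rec.y, "K": params.K,
                    "r": params.r, "M": params.M, "F": params.F,
                    "delta": params.delta, "c": params.c,
                    "bank": params.bank_present, "FST": rec.fst,
                    "FSTQ": rec.fstq, "H_T": rec.h_t, "H_S": rec.h_s,
                    "census_1": rec.census_1, "census_2": rec.census_2,
                    "extinct_flag": result.extinct,
                })
    return pd.DataFrame(rows)
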