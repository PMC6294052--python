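"""Headline simulation summaries at desk scale.

Each function reruns one of the package's headline experiments from scratch
— persistent founder effects under migration, and the fixation timing of
locally adapted alleles with and without a diapausing egg bank — at reduced
replicate counts, and reduces the trajectories to a single number.  The
``targets`` CLI subcommand and ``scripts/acceptance.py`` both call
:func:`run_targets`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .engine import SimulationParams, run_replicate
from .stats import time_to_plateau

__all__ = [
    "mean_final_fst",
    "mean_trajectory",
    "fixation_generation",
    "mean_initial_fst",
    "saturation_generation",
    "run_targets",
]

_DEFAULT_REPLICATES = 10


def _replicate_seeds(seed: int | None, count: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=count)]


def mean_trajectory(params: SimulationParams, seed: int | None,
                    replicates: int = _DEFAULT_REPLICATES,
                    attr: str = "fst") -> np.ndarray:
    """Mean FST (or FSTQ) trajectory over seeded replicates.

    Extinct replicates are excluded, matching how trajectory summaries are
    averaged elsewhere in the package.
    """
    trajs = []
    for rep_seed in _replicate_seeds(seed, replicates):
        result = run_replicate(params, rep_seed)
        if result.extinct:
            continue
        trajs.append(result.trajectory(attr))
    if not trajs:
        raise RuntimeError("all replicates went extinct")
    return np.nanmean(np.vstack(trajs), axis=0)


def mean_final_fst(params: SimulationParams, seed: int | None,
                   replicates: int = _DEFAULT_REPLICATES,
                   attr: str = "fst") -> float:
    """Mean across replicates of the final-generation FST (or FSTQ)."""
    return float(mean_trajectory(params, seed, replicates, attr)[-1])


def fixation_generation(K: float, bank_present: bool, Y: int,
                        seed: int | None,
                        replicates: int = _DEFAULT_REPLICATES,
                        delta: float = 1e-2) -> int:
    """Generation at which mean FSTQ first reaches 95% of its plateau.

    Strong locality-reversed selection (delta = 1e-2 d^-1 by default) on
    s = n = 5 unlinked selected loci, M = 2 migrant eggs per generation,
    single founding egg.  The plateau is the mean FSTQ over the final tenth
    of the trajectory.
    """
    params = SimulationParams(K=K, bank_present=bank_present, Y=Y,
                              s=5, n=5, delta=delta, c=0.5, M=2, F=1)
    traj = mean_trajectory(params, seed, replicates, attr="fstq")
    generation, _ = time_to_plateau(traj, frac=0.95, tail_frac=0.1)
    return generation


def mean_initial_fst(F: int, n_foundations: int, seed: int | None,
                     n_loci: int = 5) -> float:
    """Mean post-foundation FST over many independent double foundations.

    Each foundation draws fresh uniform source frequencies and founds both
    localities with ``F`` eggs; FST is computed from the founder genotypes
    themselves.  Foundations where FST is undefined (both localities
    monomorphic for the same alleles at every locus) are excluded.
    """
    from . import stats
    from ._state import get_space
    from .engine import SourcePopulation, found_populations

    rng = np.random.default_rng(seed)
    space = get_space(n_loci, False)
    values = []
    for _ in range(n_foundations):
        source = SourcePopulation.random(n_loci, False, rng)
        s1, s2 = found_populations(source, F, rng, space)
        p1, _ = space.allele_freqs(s1.plankton)
        p2, _ = space.allele_freqs(s2.plankton)
        v, _, _ = stats.fst_from_frequencies(p1, p2, float(F), float(F))
        values.append(v)
    return float(np.nanmean(values))


def saturation_generation(seed: int | None, K: float = 2e7,
                          frac: float = 0.95) -> int:
    """First sexual generation whose end-of-season density reaches frac*K."""
    params = SimulationParams(K=K, F=1, M=2, Y=3, s=0)
    result = run_replicate(params, seed)
    for rec in result.records:
        if max(rec.density_tau_1, rec.density_tau_2) >= frac * K:
            return rec.y
    raise RuntimeError(f"density never reached {frac:.0%} of K")


def run_targets(seed: int | None = None) -> dict[str, dict[str, float]]:
    """Recompute the headline summaries; returns {target: {value, n}}.

    t2: mean neutral FST after 1,000 generations at K = 2e7 with an egg
        bank under M = 100 migrant eggs per generation (10 replicates).
    t6: generation at which mean FSTQ reaches 95% of its plateau under
        strong selection with an egg bank, K = 2e4 (Y = 600).
    t7: same with K = 2e7 (Y = 800).
    """
    seeds = _replicate_seeds(seed, 3)
    t2_params = SimulationParams(K=2e7, bank_present=True, F=1, s=0, n=5,
                                 r=0.3, M=100, Y=1000)
    t2 = mean_final_fst(t2_params, seeds[0], replicates=10)
    t6 = fixation_generation(K=2e4, bank_present=True, Y=600, seed=seeds[1],
                             replicates=10)
    t7 = fixation_generation(K=2e7, bank_present=True, Y=800, seed=seeds[2],
                             replicates=10)
    return {
        "t2": {"value": float(t2), "n": 10},
        "t6": {"value": float(t6), "n": 10},
        "t7": {"value": float(t7), "n": 10},
    }
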