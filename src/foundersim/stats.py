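"""Population-genetic summaries: heterozygosities, FST / FSTQ, trajectories.

Differentiation between the two localities is measured with the Nei-style
fixation index

    FST = (H_T_bar - H_S_bar) / H_T_bar

where H_S_bar averages the expected heterozygosity 2p(1-p) within each
population (over loci, then over the two populations) and H_T_bar is the
expected heterozygosity of the pooled population, with pooled allele
frequencies weighted by census size ("total number of alleles").  Loci are
averaged on the heterozygosities before the single ratio is formed.  The
same statistic computed on the loci under selection is called FSTQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from . import genetics

__all__ = [
    "FstRecord",
    "expected_heterozygosity",
    "fst_from_frequencies",
    "fst",
    "delta_fst",
    "fst_fstq_association",
    "time_to_plateau",
]


@dataclass(frozen=True)
class FstRecord:
    """Per-generation snapshot taken just after hatching.

    ``fst``/``fstq`` are NaN when undefined (H_T_bar = 0, or no selected
    loci for ``fstq``).  ``census_1``/``census_2`` are the hatchling
    censuses (densities in the deterministic regime).  ``density_tau_*``
    carry the end-of-season plankton totals of the same generation once
    growth has run (NaN in the final record until the season completes).
    """

    y: int
    fst: float
    fstq: float
    h_t: float
    h_s: float
    census_1: float
    census_2: float
    density_tau_1: float = math.nan
    density_tau_2: float = math.nan


def expected_heterozygosity(p):
    """Expected heterozygosity 2p(1-p) of a biallelic locus."""
    p = np.asarray(p, dtype=np.float64)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def fst_from_frequencies(p1, p2, size1: float, size2: float
                         ) -> tuple[float, float, float]:
    """(FST, H_T_bar, H_S_bar) from per-locus allele-1 frequencies.

    ``size1``/``size2`` weight the pooled frequencies; they may be
    real-valued densities.  FST is NaN when H_T_bar is 0 (both populations
    monomorphic for the same alleles at every locus).
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=np.float64))
    p2 = np.atleast_1d(np.asarray(p2, dtype=np.float64))
    if p1.shape != p2.shape:
        raise ValueError("frequency vectors must have equal length")
    if size1 <= 0 or size2 <= 0:
        raise ValueError("population sizes must be positive")
    h_s = 0.5 * (expected_heterozygosity(p1).mean()
                 + expected_heterozygosity(p2).mean())
    pbar = (size1 * p1 + size2 * p2) / (size1 + size2)
    h_t = expected_heterozygosity(pbar).mean()
    if h_t == 0.0:
        return math.nan, 0.0, h_s
    return (h_t - h_s) / h_t, float(h_t), float(h_s)


def _freqs_from_tallies(counts: Mapping[genetics.Genotype, float],
                        subset: str) -> np.ndarray:
    total = 0.0
    sums = None
    ai = {"neutral": 0, "selected": 1}[subset]
    for g, w in counts.items():
        if w < 0:
            raise ValueError("genotype tallies must be non-negative")
        if w == 0:
            continue
        if sums is None:
            sums = np.zeros(len(g))
        for j, pair in enumerate(g.pairs):
            sums[j] += w * (pair.h1[ai] + pair.h2[ai])
        total += w
    if sums is None:
        raise ValueError("population is empty")
    return sums / (2.0 * total)


def fst(pop1_counts: Mapping[genetics.Genotype, float],
        pop2_counts: Mapping[genetics.Genotype, float],
        loci: str = "neutral") -> float:
    """FST (``loci="neutral"``) or FSTQ (``loci="selected"``) from tallies.

    Tallies map genotypes to counts or real-valued densities; allele
    frequencies use the total number of alleles in each population.
    """
    if loci not in ("neutral", "selected"):
        raise ValueError("loci must be 'neutral' or 'selected'")
    p1 = _freqs_from_tallies(pop1_counts, loci)
    p2 = _freqs_from_tallies(pop2_counts, loci)
    n1 = sum(pop1_counts.values())
    n2 = sum(pop2_counts.values())
    value, _, _ = fst_from_frequencies(p1, p2, n1, n2)
    return value


def delta_fst(trajectory: Sequence[float]) -> float:
    """Change in FST between the first and last recorded generation."""
    if len(trajectory) < 2:
        raise ValueError("trajectory needs at least two records")
    return float(trajectory[-1]) - float(trajectory[0])


def fst_fstq_association(replicate_finals: Sequence[tuple[float, float]]
                         ) -> tuple[float, float]:
    """(Kendall tau, Spearman rho) over replicate-level (FST, FSTQ) pairs.

    Returns (NaN, NaN) when either margin has zero variance.
    """
    arr = np.asarray(replicate_finals, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (FST, FSTQ) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    tau = sps.kendalltau(x, y).statistic
    rho = sps.spearmanr(x, y).statistic
    return float(tau), float(rho)


def time_to_plateau(mean_trajectory: Sequence[float], frac: float = 0.95,
                    tail_frac: float = 0.1) -> tuple[int, float]:
    """First generation at which a mean trajectory reaches its plateau.

    The plateau is estimated as the mean over the final ``tail_frac`` of the
    trajectory; the crossing is the first index (1-based, matching the
    sexual-generation count) where the trajectory is at least
    ``frac * plateau``.  Raises if the trajectory never crosses.
    """
    traj = np.asarray(mean_trajectory, dtype=np.float64)
    if traj.size < 10:
        raise ValueError("trajectory too short to estimate a plateau")
    tail = max(1, int(round(tail_frac * traj.size)))
    plateau = float(np.nanmean(traj[-tail:]))
    hits = np.nonzero(traj >= frac * plateau)[0]
    if hits.size == 0:
        raise ValueError("trajectory never reaches the plateau fraction")
    return int(hits[0]) + 1, plateau
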