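"""Within-generation demography: clonal growth, egg production, egg banks.

One sexual generation (typically one year) runs through a fixed sequence:
hatching of diapausing eggs, deterministic logistic growth of the clonal
plankton for ``tau`` days under a shared carrying capacity ``K``, random
union of gametes into a new cohort of diapausing eggs, age-independent
survival of the sediment bank at annual rate ``gamma``, migration of eggs
between habitats, and hatching of a fraction ``lambda`` of the
post-migration bank at the start of the next season.

Egg handling switches regime on population size: when a bank holds at least
``stochastic_threshold`` (1,000) eggs, survival and hatching are applied as
deterministic real-valued fractions; below the threshold each egg's fate is
an individual binomial trial.  The genotype composition of newly produced
eggs and of migrants is always a random draw, however large the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._state import StateSpace

try:  # JIT-compiled growth integral; scipy path is the fallback
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

STOCHASTIC_THRESHOLD = 1_000


class GrowthIntegrationError(RuntimeError):
    """Raised when the logistic integrator returns a non-finite state."""


@dataclass(frozen=True)
class DemographyParams:
    """Demographic parameter block (defaults are the rotifer-like baseline).

    r:      basal clonal growth rate (days^-1)
    K:      carrying capacity, genotype-independent (individuals)
    tau:    length of the planktonic growth season (days)
    m:      sexual proportion — fraction of females becoming sexual
    sr:     sex ratio — fraction of sexual offspring that are female
    e:      effective fecundity — diapausing eggs per sexual female
    gamma:  annual survival of eggs in the sediment
    lam:    annual hatching fraction of the sediment bank
    bank_present: whether unhatched survivors persist beyond age 1
    """

    r: float = 0.3
    K: float = 2e7
    tau: float = 60.0
    m: float = 0.7
    sr: float = 0.5
    e: float = 3.0
    gamma: float = 0.763
    lam: float = 0.046
    bank_present: bool = True
    stochastic_threshold: float = STOCHASTIC_THRESHOLD

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.e < 0:
            raise ValueError("e must be non-negative")
        for name in ("m", "sr", "gamma", "lam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def eggs_per_capita(self) -> float:
        """Diapausing eggs produced per end-of-season individual (m*sr*e)."""
        return self.m * self.sr * self.e


if _HAVE_NUMBA:

    @njit
    def _phi_integral(amounts, rates, K, tau, rtol):  # pragma: no cover
        """Adaptive Cash-Karp RK45 for dPhi/dt = 1 - sum(A exp(r Phi))/K.

        Returns NaN when the step size collapses or the iteration budget is
        exhausted (divergent instances, e.g. an over-capacity population
        dominated by negative growth rates).
        """
        t = 0.0
        u = 0.0
        h = tau / 16.0
        atol = 1e-12
        iterations = 0
        while t < tau:
            iterations += 1
            if iterations > 100_000 or h < 1e-12:
                return np.nan
            if t + h > tau:
                h = tau - t
            k1 = 1.0 - np.sum(amounts * np.exp(rates * u)) / K
            k2 = 1.0 - np.sum(amounts * np.exp(rates * (u + h * 0.2 * k1))) / K
            k3 = 1.0 - np.sum(amounts * np.exp(
                rates * (u + h * (0.075 * k1 + 0.225 * k2)))) / K
            k4 = 1.0 - np.sum(amounts * np.exp(
                rates * (u + h * (0.3 * k1 - 0.9 * k2 + 1.2 * k3)))) / K
            k5 = 1.0 - np.sum(amounts * np.exp(
                rates * (u + h * (-11.0 / 54.0 * k1 + 2.5 * k2
                                  - 70.0 / 27.0 * k3 + 35.0 / 27.0 * k4)))) / K
            k6 = 1.0 - np.sum(amounts * np.exp(
                rates * (u + h * (1631.0 / 55296.0 * k1 + 175.0 / 512.0 * k2
                                  + 575.0 / 13824.0 * k3
                                  + 44275.0 / 110592.0 * k4
                                  + 253.0 / 4096.0 * k5)))) / K
            u5 = u + h * (37.0 / 378.0 * k1 + 250.0 / 621.0 * k3
                          + 125.0 / 594.0 * k4 + 512.0 / 1771.0 * k6)
            u4 = u + h * (2825.0 / 27648.0 * k1 + 18575.0 / 48384.0 * k3
                          + 13525.0 / 55296.0 * k4 + 277.0 / 14336.0 * k5
                          + 0.25 * k6)
            err = abs(u5 - u4)
            if not np.isfinite(err):  # overflow in a trial stage: retry smaller
                h *= 0.5
                continue
            tol = atol + rtol * max(1.0, abs(u5))
            if err <= tol:
                t += h
                u = u5
            if err > 0.0:
                factor = 0.9 * (tol / err) ** 0.2
                if factor < 0.2:
                    factor = 0.2
                elif factor > 5.0:
                    factor = 5.0
                h *= factor
            else:
                h *= 5.0
        return u


def _solve_phi(amounts: np.ndarray, rates: np.ndarray, K: float, tau: float,
               rtol: float) -> float:
    """Growth integral Phi(tau) for dPhi/dt = 1 - sum_k A_k exp(r_k Phi)/K."""
    if _HAVE_NUMBA:
        return float(_phi_integral(amounts, rates, K, tau, rtol))

    def dphi(_t, phi):
        return 1.0 - np.dot(amounts, np.exp(rates * phi[0])) / K

    sol = solve_ivp(dphi, (0.0, tau), [0.0], rtol=rtol, atol=1e-12)
    if not sol.success:
        raise GrowthIntegrationError(
            f"logistic integration failed: {sol.message}")
    return float(sol.y[0, -1])


def asexual_growth(initial: np.ndarray, rates: np.ndarray, K: float,
                   tau: float, rtol: float = 1e-8) -> np.ndarray:
    """Grow all clonal lineages logistically for ``tau`` days.

    The coupled system dN_g/dt = N_g r_g (1 - sum(N)/K) shares the density
    regulation term, so every lineage scales as N_g(t) = N_g(0) exp(r_g
    Phi(t)) with a single growth integral Phi(t) = int_0^t (1 - sum(N)/K) dt.
    Phi is obtained from the scalar ODE dPhi/dt = 1 - sum_g N_g(0)
    exp(r_g Phi)/K, which is exact up to integration tolerance and
    independent of the number of genotypes.
    """
    initial = np.asarray(initial, dtype=np.float64)
    if np.any(initial < 0):
        raise ValueError("densities must be non-negative")
    total0 = initial.sum()
    if total0 == 0:
        return np.zeros_like(initial)

    live = initial > 0
    uniq, inv = np.unique(np.asarray(rates, dtype=np.float64)[live],
                          return_inverse=True)
    if uniq.size == 1:
        # single effective growth rate: closed-form logistic for the total,
        # identical scaling for every lineage
        r0 = uniq[0]
        if r0 == 0.0:
            return initial.copy()
        total_tau = K / (1.0 + (K / total0 - 1.0) * np.exp(-r0 * tau))
        return initial * (total_tau / total0)

    amounts = np.bincount(inv, weights=initial[live], minlength=uniq.size)
    phi = _solve_phi(amounts, uniq, K, tau, rtol)
    if not np.isfinite(phi):
        raise GrowthIntegrationError("non-finite growth integral")
    out = np.zeros_like(initial)
    out[live] = initial[live] * np.exp(np.asarray(rates, dtype=np.float64)[live] * phi)
    if not np.all(np.isfinite(out)):
        raise GrowthIntegrationError("non-finite densities after growth")
    return out


def produce_eggs(plankton_tau: np.ndarray, params: DemographyParams,
                 space: StateSpace, c: float,
                 rng: np.random.Generator) -> np.ndarray:
    """New diapausing-egg cohort from the end-of-season plankton.

    The cohort totals round(sum(N(tau)) * m * sr * e) eggs; its genotype
    composition is a multinomial draw of random gamete unions from the
    panmictic pool — stochastic at any population size.  An extinct plankton
    yields an empty cohort.
    """
    total = float(np.sum(plankton_tau))
    n_eggs = int(round(total * params.eggs_per_capita))
    if total <= 0 or n_eggs == 0:
        return np.zeros(space.n_genotypes)
    pool = space.gamete_pool(np.asarray(plankton_tau, dtype=np.float64), c)
    return space.sample_eggs(pool, n_eggs, rng)


def _apply_fraction(counts: np.ndarray, frac: float, threshold: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Thin ``counts`` by ``frac``: deterministic above threshold, binomial below."""
    total = counts.sum()
    if total <= 0 or frac == 0.0:
        return np.zeros_like(counts)
    if total >= threshold:
        return counts * frac
    ints = np.rint(counts).astype(np.int64)
    return rng.binomial(ints, frac).astype(np.float64)


def bank_survive(bank: np.ndarray, params: DemographyParams,
                 rng: np.random.Generator) -> np.ndarray:
    """One year of age-independent sediment mortality (survival gamma)."""
    return _apply_fraction(np.asarray(bank, dtype=np.float64), params.gamma,
                           params.stochastic_threshold, rng)


def bank_hatch(bank: np.ndarray, params: DemographyParams,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Start-of-season hatching: a fraction ``lam`` of the bank hatches.

    Returns ``(hatched, remaining_bank)``.  Without a bank the unhatched
    remainder is discarded — eggs older than one year are dead.
    """
    bank = np.asarray(bank, dtype=np.float64)
    total = bank.sum()
    if total <= 0:
        return np.zeros_like(bank), np.zeros_like(bank)
    if total >= params.stochastic_threshold:
        hatched = bank * params.lam
        remaining = bank - hatched
    else:
        ints = np.rint(bank).astype(np.int64)
        hatched = rng.binomial(ints, params.lam).astype(np.float64)
        remaining = ints - hatched
    if not params.bank_present:
        remaining = np.zeros_like(bank)
    return hatched, remaining


def bank_update(bank: np.ndarray, new_cohort: np.ndarray,
                params: DemographyParams,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Yearly bank turnover without migration: survival then hatching.

    Each egg survives the year with probability gamma and then hatches with
    probability lam; survivors that do not hatch stay in the bank when one is
    present.  Convenience composition of :func:`bank_survive` and
    :func:`bank_hatch` for closed (migration-free) populations.
    """
    combined = np.asarray(bank, dtype=np.float64) + np.asarray(new_cohort,
                                                              dtype=np.float64)
    survivors = bank_survive(combined, params, rng)
    return bank_hatch(survivors, params, rng)


def migrate(donor_bank: np.ndarray, n_migrants: int,
            rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_migrants`` eggs from a donor bank's genotype distribution.

    Migrant selection is random regardless of numbers; the donor bank is not
    depleted (emigration is negligible relative to bank size).  An empty
    donor sends nothing.
    """
    if n_migrants < 0:
        raise ValueError("migrant count must be non-negative")
    donor_bank = np.asarray(donor_bank, dtype=np.float64)
    total = donor_bank.sum()
    if n_migrants == 0 or total <= 0:
        return np.zeros_like(donor_bank)
    p = donor_bank / total
    return rng.multinomial(int(n_migrants), p).astype(np.float64)
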