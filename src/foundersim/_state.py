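"""Array-indexed genotype state space.

The simulation engine tracks each population as a dense vector of densities
(or egg counts) indexed by genotype.  With ``n`` locus pairs there are
``10**n`` genotypes when selected loci are present (10 unordered,
phase-preserving diplotype states per pair) and ``3**n`` when the scenario is
purely neutral.  This module precomputes the lookup tables that make the
per-generation operations — gamete-pool computation, random union of gametes
into diapausing eggs, allele-frequency readout, fitness grouping — plain
numpy array work.

The per-pair gamete probabilities are taken from
:func:`foundersim.genetics.gamete_distribution`, so the vectorized path and
the object API cannot drift apart.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from . import genetics

try:  # JIT scatter kernel for the random-union genotype distribution
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @njit
    def _egg_probs_kernel(pool, pair_map, out):  # pragma: no cover
        """out[g] = sum over unordered haplotype pairs mapping to g."""
        H = pool.shape[0]
        for i in range(H):
            pi = pool[i]
            if pi == 0.0:
                continue
            out[pair_map[i, i]] += pi * pi
            for j in range(i + 1, H):
                pj = pool[j]
                if pj != 0.0:
                    out[pair_map[i, j]] += 2.0 * pi * pj
        return out


class StateSpace:
    """Lookup tables for the genotype space of ``n`` locus pairs.

    Parameters
    ----------
    n:
        Number of locus pairs (neutral loci; also selected loci when
        ``selected``).
    selected:
        Whether each pair carries a selected locus (``s = n``) or only the
        neutral marker (``s = 0``).
    """

    def __init__(self, n: int, selected: bool):
        if n < 1:
            raise ValueError("need at least one locus pair")
        self.n = n
        self.selected = selected
        # Per-pair haplotypes, indexed. Selected: (neutral, selected) with
        # index 2*a_n + a_s; neutral-only: (a_n,) with index a_n.
        if selected:
            self.pair_haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
        else:
            self.pair_haps = [(0,), (1,)]
        self.n_hap_pair = len(self.pair_haps)
        # Per-pair diplotype states: unordered pairs of per-pair haplotypes.
        self.pair_states = [
            (i, j)
            for i in range(self.n_hap_pair)
            for j in range(i, self.n_hap_pair)
        ]
        self.n_state_pair = len(self.pair_states)  # 10 or 3
        self.n_genotypes = self.n_state_pair ** n
        self.n_haplotypes = self.n_hap_pair ** n

        # state index lookup for an (ordered) pair of per-pair haplotypes
        self._pair_state_of = np.empty((self.n_hap_pair, self.n_hap_pair),
                                       dtype=np.int64)
        for k, (i, j) in enumerate(self.pair_states):
            self._pair_state_of[i, j] = k
            self._pair_state_of[j, i] = k

        # genotype index <-> per-pair state digits (mixed radix, big-endian)
        radix = self.n_state_pair
        self._radix_pow = radix ** np.arange(n - 1, -1, -1)
        idx = np.arange(self.n_genotypes)
        self.digits = (idx[:, None] // self._radix_pow[None, :]) % radix

        # per-pair-state allele copy counts
        copies_n = np.empty(self.n_state_pair, dtype=np.int8)
        copies_s = np.zeros(self.n_state_pair, dtype=np.int8)
        for k, (i, j) in enumerate(self.pair_states):
            h1, h2 = self.pair_haps[i], self.pair_haps[j]
            copies_n[k] = h1[0] + h2[0]
            if selected:
                copies_s[k] = h1[1] + h2[1]
        #: (n_genotypes, n) copies of allele 1 at each neutral locus
        self.neutral_copies = copies_n[self.digits]
        #: (n_genotypes, n) copies of allele 1 at each selected locus
        self.sel_copies = copies_s[self.digits]
        #: total selected-allele-1 copies per genotype (0..2n)
        self.sel_total = self.sel_copies.sum(axis=1).astype(np.int64)

        # haplotype index <-> per-pair haplotype digits
        hradix = self.n_hap_pair
        self._hradix_pow = hradix ** np.arange(n - 1, -1, -1)
        hidx = np.arange(self.n_haplotypes)
        self.hap_digits = (hidx[:, None] // self._hradix_pow[None, :]) % hradix

        # genotype index of every ordered pair of full haplotypes
        pair_digit_state = self._pair_state_of[
            self.hap_digits[:, None, :], self.hap_digits[None, :, :]
        ]  # (n_hap, n_hap, n)
        self.genotype_of_hap_pair = (
            pair_digit_state * self._radix_pow[None, None, :]
        ).sum(axis=2).astype(np.int32)
        self._flat_hap_pair_map = self.genotype_of_hap_pair.ravel()

    # -- conversions ------------------------------------------------------

    def genotype_at(self, index: int) -> genetics.Genotype:
        """The :class:`~foundersim.genetics.Genotype` object at an index."""
        pairs = []
        for d in self.digits[index]:
            i, j = self.pair_states[d]
            pairs.append(
                genetics.PairDiplotype(self.pair_haps[i], self.pair_haps[j])
            )
        return genetics.Genotype(tuple(pairs))

    def index_of(self, g: genetics.Genotype) -> int:
        if len(g) != self.n or g.has_selected != self.selected:
            raise ValueError("genotype does not belong to this state space")
        idx = 0
        hap_index = {h: k for k, h in enumerate(self.pair_haps)}
        for d, pair in enumerate(g.pairs):
            k = self._pair_state_of[hap_index[pair.h1], hap_index[pair.h2]]
            idx += int(k) * int(self._radix_pow[d])
        return idx

    def haplotype_at(self, index: int) -> genetics.Haplotype:
        return tuple(self.pair_haps[d] for d in self.hap_digits[index])

    # -- gamete machinery -------------------------------------------------

    @lru_cache(maxsize=16)
    def pair_transition(self, c: float) -> np.ndarray:
        """(n_state_pair, n_hap_pair) per-pair gamete probabilities.

        Row k is the gamete distribution of single-pair state k under
        recombination fraction c, computed from the object API.
        """
        T = np.zeros((self.n_state_pair, self.n_hap_pair))
        hap_index = {h: k for k, h in enumerate(self.pair_haps)}
        for k, (i, j) in enumerate(self.pair_states):
            pd = genetics.PairDiplotype(self.pair_haps[i], self.pair_haps[j])
            for hap, p in pd.gamete_probs(c).items():
                T[k, hap_index[hap]] += p
        return T

    def gamete_pool(self, weights: np.ndarray, c: float) -> np.ndarray:
        """Pooled gametic frequencies over all ``n_haplotypes`` haplotypes.

        ``weights`` is the genotype-indexed density/count vector of the
        sexual adults.  The pool is the weight-averaged mixture of per-parent
        gamete distributions; it generally does not factorize across pairs
        (gametes from one parent share that parent's multilocus genotype).
        """
        total = float(weights.sum())
        if total <= 0:
            raise genetics.EmptyPoolError(
                "gamete pool requested from an empty population"
            )
        T = self.pair_transition(c)
        W = (weights / total).reshape((self.n_state_pair,) * self.n)
        # Contract each pair axis with T: leading state axis -> trailing hap
        # axis, which keeps pair order after n contractions.
        for _ in range(self.n):
            W = np.tensordot(W, T, axes=([0], [0]))
        return W.reshape(-1)

    def egg_probs(self, pool: np.ndarray) -> np.ndarray:
        """Genotype distribution of eggs from random union of two gametes."""
        if _HAVE_NUMBA:
            out = np.zeros(self.n_genotypes)
            return _egg_probs_kernel(pool, self.genotype_of_hap_pair, out)
        outer = np.multiply.outer(pool, pool).ravel()
        return np.bincount(self._flat_hap_pair_map, weights=outer,
                           minlength=self.n_genotypes)

    # -- sampling and readout --------------------------------------------

    def sample_eggs(self, pool: np.ndarray, n_eggs: int,
                    rng: np.random.Generator) -> np.ndarray:
        """Draw ``n_eggs`` eggs, each a random union of two pool gametes."""
        q = self.egg_probs(pool)
        q = q / q.sum()
        return rng.multinomial(n_eggs, q).astype(np.float64)

    def sample_hwe(self, neutral_freqs: np.ndarray,
                   sel_freqs: np.ndarray | None, n_draws: int,
                   rng: np.random.Generator) -> np.ndarray:
        """Genotype counts of ``n_draws`` individuals drawn at HWE.

        Haplotypes are drawn at linkage equilibrium from per-locus allele-1
        frequencies — the infinite, fully neutral source population.
        """
        a_n = rng.random((n_draws, self.n, 2)) < np.asarray(neutral_freqs)[None, :, None]
        if self.selected:
            if sel_freqs is None:
                raise ValueError("selected-locus frequencies required")
            a_s = rng.random((n_draws, self.n, 2)) < np.asarray(sel_freqs)[None, :, None]
            hap_idx = 2 * a_n.astype(np.int64) + a_s.astype(np.int64)
        else:
            hap_idx = a_n.astype(np.int64)
        states = self._pair_state_of[hap_idx[:, :, 0], hap_idx[:, :, 1]]
        gidx = (states * self._radix_pow[None, :]).sum(axis=1)
        return np.bincount(gidx, minlength=self.n_genotypes).astype(np.float64)

    def allele_freqs(self, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Per-locus allele-1 frequencies implied by a genotype weight vector.

        Returns ``(neutral, selected)``; ``selected`` is None for neutral
        spaces.  Weights may be fractional densities.
        """
        total = weights.sum()
        if total <= 0:
            raise ValueError("cannot compute allele frequencies of an empty population")
        p_n = (weights @ self.neutral_copies) / (2.0 * total)
        if not self.selected:
            return p_n, None
        p_s = (weights @ self.sel_copies) / (2.0 * total)
        return p_n, p_s

    def growth_rates(self, r: float, delta: float, locality: int) -> np.ndarray:
        """Per-genotype intrinsic growth rate r + theta in a locality.

        theta follows the locality-reversed additive scheme: each selected
        locus contributes +2*delta (favored homozygote), 0 (heterozygote) or
        -2*delta (disfavored homozygote); allele 1 is favored in locality 1.
        """
        if locality not in (1, 2):
            raise ValueError(f"locality must be 1 or 2, got {locality}")
        if not self.selected:
            return np.full(self.n_genotypes, float(r))
        sign = 1.0 if locality == 1 else -1.0
        # each locus: 2*(copies-1)*delta, i.e. +2d / 0 / -2d
        return r + sign * 2.0 * delta * (self.sel_total - self.n)

    def enumerate_genotypes(self):
        """Iterate over (index, Genotype) — intended for small n."""
        for i in range(self.n_genotypes):
            yield i, self.genotype_at(i)


@lru_cache(maxsize=8)
def get_space(n: int, selected: bool) -> StateSpace:
    """Memoized StateSpace — the tables are reused across replicates."""
    return StateSpace(n, selected)
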