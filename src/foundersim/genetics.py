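"""Genotypes, fitness deviations, and gamete distributions.

Each individual carries ``n`` locus pairs.  A pair couples one biallelic
neutral marker to one biallelic locus under selection, physically linked with
recombination fraction ``c``; distinct pairs assort independently.  In purely
neutral scenarios (``s = 0``) the selected locus of every pair is absent and a
haplotype reduces to its neutral allele.  There is no mutation, no dominance
and no epistasis: selected loci act additively on the clonal growth rate.

A per-pair haplotype is a tuple ``(neutral_allele,)`` or
``(neutral_allele, selected_allele)`` with alleles in ``{0, 1}``.  A full
:class:`Haplotype` is the tuple of per-pair haplotypes.  Diploid state is held
per pair as an unordered (but phase-preserving) :class:`PairDiplotype`; a
:class:`Genotype` is the vector of its ``n`` pair diplotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "Haplotype",
    "PairHaplotype",
    "PairDiplotype",
    "Genotype",
    "SelectionScheme",
    "EmptyPoolError",
    "theta",
    "gamete_distribution",
    "gamete_pool",
]

#: A single-pair haplotype: (neutral,) or (neutral, selected).
PairHaplotype = tuple
#: A full haplotype: one PairHaplotype per locus pair.
Haplotype = tuple


class EmptyPoolError(ValueError):
    """Raised when a gamete pool is requested from an extinct population."""


@dataclass(frozen=True)
class PairDiplotype:
    """Unordered pair of single-pair haplotypes at one locus pair.

    Phase within the pair is preserved: the cis double heterozygote
    ``{(0,0),(1,1)}`` and the trans one ``{(0,1),(1,0)}`` are distinct
    states.  With a selected locus present there are exactly 10 states per
    pair (4 homozygous combinations where order is irrelevant plus 6
    unordered heterozygous combinations); without one there are 3.
    """

    h1: PairHaplotype
    h2: PairHaplotype

    def __post_init__(self) -> None:
        if len(self.h1) != len(self.h2):
            raise ValueError("haplotypes of a pair must have equal arity")
        for h in (self.h1, self.h2):
            if not all(a in (0, 1) for a in h):
                raise ValueError(f"alleles must be 0/1, got {h!r}")
        if self.h2 < self.h1:  # canonical order makes the pair unordered
            h1, h2 = self.h1, self.h2
            object.__setattr__(self, "h1", h2)
            object.__setattr__(self, "h2", h1)

    @property
    def has_selected(self) -> bool:
        return len(self.h1) == 2

    def gamete_probs(self, c: float) -> dict[PairHaplotype, float]:
        """Gamete distribution of this pair under recombination fraction c."""
        if not 0.0 <= c <= 0.5:
            raise ValueError(f"recombination rate must be in [0, 0.5], got {c}")
        probs: dict[PairHaplotype, float] = {}
        if not self.has_selected:
            for h in (self.h1, self.h2):
                probs[h] = probs.get(h, 0.0) + 0.5
            return probs
        rec1 = (self.h1[0], self.h2[1])
        rec2 = (self.h2[0], self.h1[1])
        for h, p in ((self.h1, (1 - c) / 2), (self.h2, (1 - c) / 2),
                     (rec1, c / 2), (rec2, c / 2)):
            probs[h] = probs.get(h, 0.0) + p
        return probs


@dataclass(frozen=True)
class Genotype:
    """Diploid multilocus genotype: one :class:`PairDiplotype` per pair.

    Phase *across* pairs is not represented; under independent assortment it
    never affects gamete output, so the tuple of per-pair states is a
    sufficient description.
    """

    pairs: tuple[PairDiplotype, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("genotype needs at least one locus pair")
        arity = self.pairs[0].has_selected
        if any(p.has_selected != arity for p in self.pairs):
            raise ValueError("all pairs must share the same locus arity")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def has_selected(self) -> bool:
        return self.pairs[0].has_selected


@dataclass(frozen=True)
class SelectionScheme:
    """Locality-reversed additive selection on the growth rate.

    ``delta`` (days^-1) is the additive effect of one allele copy.  The fixed
    convention is that allele 1 is favored in locality 1 and allele 0 in
    locality 2; effects are antisymmetric across alleles and mirrored across
    localities, so a homozygote gains or loses 2*delta at each selected locus
    depending on where it lives.
    """

    delta: float

    FAVORED_ALLELE = {1: 1, 2: 0}

    def allele_effect(self, allele: int, locality: int) -> float:
        if locality not in (1, 2):
            raise ValueError(f"locality must be 1 or 2, got {locality}")
        return self.delta if allele == self.FAVORED_ALLELE[locality] else -self.delta


def theta(g: Genotype, locality: int, scheme: SelectionScheme) -> float:
    """Growth-rate deviation of genotype ``g`` in ``locality`` (days^-1).

    Sums the additive effect of every selected-allele copy the genotype
    carries; with ``s`` selected loci the result lies in ``[-2*s*delta,
    +2*s*delta]``, and neutral alleles never contribute.  Genotypes without
    selected loci return 0.
    """
    if locality not in (1, 2):
        raise ValueError(f"locality must be 1 or 2, got {locality}")
    if not g.has_selected:
        return 0.0
    total = 0.0
    for pair in g.pairs:
        total += scheme.allele_effect(pair.h1[1], locality)
        total += scheme.allele_effect(pair.h2[1], locality)
    return total


def gamete_distribution(g: Genotype, c: float) -> dict[Haplotype, float]:
    """Probability distribution over gametes produced by genotype ``g``.

    Recombination at fraction ``c`` acts within each neutral–selected pair;
    pairs assort independently, so the distribution factorizes across pairs.
    """
    per_pair = [pair.gamete_probs(c) for pair in g.pairs]
    dist: dict[Haplotype, float] = {}
    for combo in itertools.product(*(p.items() for p in per_pair)):
        hap = tuple(h for h, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        dist[hap] = dist.get(hap, 0.0) + prob
    return dist


def gamete_pool(
    genotype_weights: Mapping[Genotype, float] | Iterable[tuple[Genotype, float]],
    c: float,
) -> dict[Haplotype, float]:
    """Gamete pool of a panmictic population: weight-averaged gamete output.

    ``genotype_weights`` maps each genotype to a non-negative weight (a
    density or a count).  Raises :class:`EmptyPoolError` when all weights are
    zero — a population with no adults cannot reproduce sexually.
    """
    items = list(genotype_weights.items()) if isinstance(genotype_weights, Mapping) \
        else list(genotype_weights)
    total = 0.0
    pool: dict[Haplotype, float] = {}
    for g, w in items:
        if w < 0:
            raise ValueError("genotype weights must be non-negative")
        if w == 0:
            continue
        total += w
        for hap, p in gamete_distribution(g, c).items():
            pool[hap] = pool.get(hap, 0.0) + w * p
    if total <= 0:
        raise EmptyPoolError("gamete pool requested from an empty population")
    return {hap: p / total for hap, p in pool.items()}
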