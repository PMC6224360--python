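"""Core probability engine for tetraploid meiosis at a single locus.

An allotetraploid carries four chromosome copies per locus, two inherited from
each ancestral genome (labelled ``M`` for the mandarin-derived pair and ``P``
for the poncirus-derived pair).  At meiosis the four copies resolve into two
diploid-gamete alleles, and the distribution of gamete allele classes is
modelled as a three-component mixture:

* with probability ``1 - tau`` the locus segregates *disomically* under a fixed
  pairing scenario: each of the two pairs contributes exactly one copy, the
  four copy combinations being equiprobable;
* with probability ``tau * (1 - beta)`` chromosomes associate at random
  (*tetrasomic* bivalent segregation): the gamete receives one of the six
  unordered copy pairs, equiprobably;
* with probability ``tau * beta`` the gamete is a *double-reduction* product:
  a single copy, drawn uniformly from the four, is transmitted twice.

``tau`` therefore measures the proportion of gametes explicable by random
chromosome association (0 = strict disomy, 1 = full tetrasomy) and ``beta``
the double-reduction frequency relative to that tetrasomic fraction.

Copy-level outcomes are collapsed to unordered allele multisets ("gamete
classes"); the null allele ``"0"`` is an ordinary symbol at this level.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "NULL_ALLELE",
    "GENOME_LABELS",
    "Allele",
    "GameteClass",
    "gamete_class",
    "ChromosomeCopy",
    "TetraploidGenotype",
    "PairingScenario",
    "SegregationParams",
    "ClassDistribution",
    "enumerate_scenarios",
    "disomic_distribution",
    "random_pairing_distribution",
    "double_reduction_distribution",
    "gamete_class_distribution",
    "expected_intergeneric_het",
]

Allele = str
NULL_ALLELE: Allele = "0"
GENOME_LABELS: Tuple[str, str] = ("M", "P")

#: A diploid gamete class: an unordered multiset of two allele symbols,
#: canonically stored as a sorted tuple so that AB == BA.
GameteClass = Tuple[Allele, Allele]

#: A gamete-class distribution: probabilities keyed by class.
ClassDistribution = Dict[GameteClass, float]


def gamete_class(a: Allele, b: Allele) -> GameteClass:
    """Canonical (sorted) representation of the unordered allele pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ChromosomeCopy:
    """One of the four chromosome copies at a locus.

    ``allele`` is an opaque, case-sensitive symbol; ``"0"`` denotes a null
    (non-amplifying) allele and participates in all computations as an
    ordinary symbol.  ``origin`` is the ancestral genome label and
    ``copy_index`` (1 or 2) identifies the copy within its genome, so that the
    same index refers to the same physical chromosome across loci.
    """

    allele: Allele
    origin: str
    copy_index: int

    def __post_init__(self) -> None:
        if self.origin not in GENOME_LABELS:
            raise ValueError(f"origin must be one of {GENOME_LABELS}, got {self.origin!r}")
        if self.copy_index not in (1, 2):
            raise ValueError(f"copy_index must be 1 or 2, got {self.copy_index!r}")


@dataclass(frozen=True)
class TetraploidGenotype:
    """The four chromosome copies of a tetraploid at one locus."""

    locus_name: str
    copies: Tuple[ChromosomeCopy, ChromosomeCopy, ChromosomeCopy, ChromosomeCopy]
    linkage_group: int = 0

    def __post_init__(self) -> None:
        if len(self.copies) != 4:
            raise ValueError("a tetraploid genotype needs exactly four chromosome copies")
        for genome in GENOME_LABELS:
            n = sum(1 for c in self.copies if c.origin == genome)
            if n != 2:
                raise ValueError(
                    f"expected two copies of genome {genome!r} at {self.locus_name}, found {n}"
                )

    @classmethod
    def from_parents(
        cls,
        locus_name: str,
        m_alleles: Iterable[Allele],
        p_alleles: Iterable[Allele],
        linkage_group: int = 0,
    ) -> "TetraploidGenotype":
        """Build a genotype from the two diploid fusion parents.

        ``m_alleles``/``p_alleles`` are the two-allele genotypes of the
        mandarin-like and poncirus-like parent, e.g. ``"BC"`` and ``"AA"``
        (any iterable of two symbols is accepted, so multi-character allele
        names work too).
        """
        m = tuple(m_alleles)
        p = tuple(p_alleles)
        if len(m) != 2 or len(p) != 2:
            raise ValueError("each diploid parent contributes exactly two alleles")
        copies = (
            ChromosomeCopy(m[0], "M", 1),
            ChromosomeCopy(m[1], "M", 2),
            ChromosomeCopy(p[0], "P", 1),
            ChromosomeCopy(p[1], "P", 2),
        )
        return cls(locus_name, copies, linkage_group)

    @property
    def alleles(self) -> Tuple[Allele, ...]:
        """The four allele symbols (with repeats), sorted."""
        return tuple(sorted(c.allele for c in self.copies))

    def alleles_of(self, genome: str) -> Tuple[Allele, ...]:
        return tuple(sorted(c.allele for c in self.copies if c.origin == genome))

    @property
    def allele_multiplicity(self) -> Dict[Allele, int]:
        mult: Dict[Allele, int] = {}
        for c in self.copies:
            mult[c.allele] = mult.get(c.allele, 0) + 1
        return mult

    @property
    def is_fully_differentiating(self) -> bool:
        """True if no allele symbol is shared between the two genomes."""
        return not set(self.alleles_of("M")) & set(self.alleles_of("P"))

    @property
    def origin_map(self) -> Dict[Allele, str]:
        """allele -> genome label; only defined for fully differentiating loci."""
        if not self.is_fully_differentiating:
            raise ValueError(
                f"locus {self.locus_name}: allele shared between genomes, origin is ambiguous"
            )
        return {c.allele: c.origin for c in self.copies}


@dataclass(frozen=True)
class PairingScenario:
    """A partition of the four copies (by index into ``copies``) into two pairs.

    ``is_homologous`` is true iff each pair unites the two copies of one
    genome — the pairing expected under strict preferential (disomic)
    behaviour of an allotetraploid.
    """

    pairs: Tuple[Tuple[int, int], Tuple[int, int]]
    is_homologous: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return " | ".join("".join(str(i) for i in pair) for pair in self.pairs)


@dataclass(frozen=True)
class SegregationParams:
    """Mixture parameters: ``tau`` in [0,1], ``beta`` in [0,1].

    The overall double-reduction proportion is ``tau * beta``.  Its biological
    ceiling under systematic quadrivalent formation is 1/6; values above it
    are allowed by the model but flagged via :attr:`exceeds_dr_ceiling`.
    """

    tau: float
    beta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau must lie in [0, 1], got {self.tau}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")

    @property
    def double_reduction_rate(self) -> float:
        return self.tau * self.beta

    @property
    def exceeds_dr_ceiling(self) -> bool:
        return self.double_reduction_rate > 1.0 / 6.0


_PARTITIONS: Tuple[Tuple[Tuple[int, int], Tuple[int, int]], ...] = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)


def _scenario(genotype: TetraploidGenotype, pairs) -> PairingScenario:
    homologous = all(
        genotype.copies[i].origin == genotype.copies[j].origin for i, j in pairs
    )
    return PairingScenario(pairs=pairs, is_homologous=homologous)


def disomic_distribution(
    genotype: TetraploidGenotype, scenario: PairingScenario
) -> Dict[GameteClass, Fraction]:
    """Exact disomic class distribution: one copy from each pair, 4 equiprobable."""
    (i, j), (k, l) = scenario.pairs
    dist: Dict[GameteClass, Fraction] = {}
    q = Fraction(1, 4)
    for a in (i, j):
        for b in (k, l):
            cls = gamete_class(genotype.copies[a].allele, genotype.copies[b].allele)
            dist[cls] = dist.get(cls, Fraction(0)) + q
    return dist


def random_pairing_distribution(
    genotype: TetraploidGenotype,
) -> Dict[GameteClass, Fraction]:
    """Random chromosome (bivalent) segregation: 6 equiprobable copy pairs."""
    dist: Dict[GameteClass, Fraction] = {}
    q = Fraction(1, 6)
    for a, b in combinations(range(4), 2):
        cls = gamete_class(genotype.copies[a].allele, genotype.copies[b].allele)
        dist[cls] = dist.get(cls, Fraction(0)) + q
    return dist


def double_reduction_distribution(
    genotype: TetraploidGenotype,
) -> Dict[GameteClass, Fraction]:
    """Double reduction: a doubled single copy, 4 equiprobable."""
    dist: Dict[GameteClass, Fraction] = {}
    q = Fraction(1, 4)
    for c in genotype.copies:
        cls = gamete_class(c.allele, c.allele)
        dist[cls] = dist.get(cls, Fraction(0)) + q
    return dist


def enumerate_scenarios(
    genotype: TetraploidGenotype,
) -> List[Tuple[PairingScenario, int]]:
    """All three pairing scenarios with symbolic equivalence-class ids.

    Two scenarios are equivalent when they produce identical class
    distributions for every (tau, beta).  Since the tetrasomic and
    double-reduction components are scenario-independent, this reduces to
    equality of the exact disomic distributions, compared at the allele level
    with rational arithmetic.
    """
    scenarios = [_scenario(genotype, pairs) for pairs in _PARTITIONS]
    signatures = [frozenset(disomic_distribution(genotype, s).items()) for s in scenarios]
    ids: List[int] = []
    seen: List[frozenset] = []
    for sig in signatures:
        for eq_id, known in enumerate(seen):
            if sig == known:
                ids.append(eq_id)
                break
        else:
            seen.append(sig)
            ids.append(len(seen) - 1)
    return list(zip(scenarios, ids))


def homologous_scenario(genotype: TetraploidGenotype) -> PairingScenario:
    """The unique scenario pairing each genome's two copies together."""
    for scenario, _ in enumerate_scenarios(genotype):
        if scenario.is_homologous:
            return scenario
    raise AssertionError("unreachable: one partition is always homologous")


def gamete_class_distribution(
    genotype: TetraploidGenotype,
    scenario: PairingScenario,
    params: SegregationParams,
) -> ClassDistribution:
    """Gamete-class probabilities under the disomic/tetrasomic/DR mixture.

    ``P(class) = (1-tau) P_dis + tau [(1-beta) P_chrom + beta P_DR]``
    with the three mode distributions defined module-level.
    """
    tau, beta = params.tau, params.beta
    dist: Dict[GameteClass, float] = {}
    for cls, p in disomic_distribution(genotype, scenario).items():
        dist[cls] = dist.get(cls, 0.0) + (1.0 - tau) * float(p)
    for cls, p in random_pairing_distribution(genotype).items():
        dist[cls] = dist.get(cls, 0.0) + tau * (1.0 - beta) * float(p)
    for cls, p in double_reduction_distribution(genotype).items():
        dist[cls] = dist.get(cls, 0.0) + tau * beta * float(p)
    return {cls: p for cls, p in dist.items() if p > 0.0}


def expected_intergeneric_het(params: SegregationParams) -> float:
    """Probability that a gamete unites one M and one P allele.

    Holds for a fully genus-differentiating locus under the homologous
    pairing scenario: disomy always transmits one copy per genome; random
    bivalent pairing does so with probability 2/3; double reduction never
    does.  Hence ``1 - tau/3 - (2/3) tau beta``.
    """
    return 1.0 - params.tau / 3.0 - (2.0 / 3.0) * params.tau * params.beta
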