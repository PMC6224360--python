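"""Generative model of tetraploid meiosis and triploid progeny formation.

Emulates the study design: a tetraploid somatic hybrid produces diploid
pollen gametes at codominant marker loci spread over linkage groups; each
gamete is fused with one maternal allele from a diploid seed parent to give a
dosage-annotated triploid progeny record.

Per gamete and per linkage group a meiotic mode is drawn with probabilities
``(1 - tau, tau (1 - beta), tau beta)``:

* *disomic* — the two copies of each genome pair; one genus-constant
  haplotype per genome is transmitted intact;
* *chromosomal* (random bivalent pairing) — one of the three pairings of the
  four chromosomes is drawn; heterogenomic bivalents may exchange between
  adjacent loci with a configurable crossover probability, producing
  genus-switching haplotypes;
* *double reduction* — one chromosome is transmitted twice at a designated
  focal locus of the linkage group (elsewhere the gamete follows the random
  pairing draw).

Single-locus marginal class frequencies match
:func:`tetragam.model.gamete_class_distribution`; with double reduction the
match is exact at the focal locus (non-focal loci follow the beta = 0
marginal, since double reduction is a locus-specific event).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inference import LocusCounts, MaternalGenotype, validate_maternal
from .model import (
    NULL_ALLELE,
    GameteClass,
    PairingScenario,
    SegregationParams,
    TetraploidGenotype,
    gamete_class,
    gamete_class_distribution,
)

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "SimulatedGamete",
    "simulate_gametes_single_locus",
    "simulate_multilocus",
    "fuse_with_maternal",
]

_PARTITIONS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass(frozen=True)
class LocusSpec:
    """One simulated marker: parental constitution plus maternal genotype."""

    genotype: TetraploidGenotype
    maternal: MaternalGenotype
    position: int = 0  # order along the linkage group


@dataclass
class SimulationConfig:
    """Study-level simulation settings.

    ``tau_by_lg``/``beta_by_lg`` give the mixture parameters per linkage
    group; ``crossover_prob`` is the per-adjacent-interval probability of an
    intergeneric exchange within a heterogenomic bivalent.  ``dr_focal``
    optionally names the focal locus per LG for double reduction (defaults
    to the first locus of the group).
    """

    loci: List[LocusSpec]
    tau_by_lg: Dict[int, float]
    beta_by_lg: Dict[int, float]
    crossover_prob: float = 0.25
    n_gametes: int = 58
    seed: int = 0
    dr_focal: Optional[Dict[int, str]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_prob <= 1.0:
            raise ValueError("crossover_prob must lie in [0, 1]")
        if self.n_gametes < 1:
            raise ValueError("n_gametes must be positive")
        for lg in {spec.genotype.linkage_group for spec in self.loci}:
            tau = self.tau_by_lg.get(lg)
            beta = self.beta_by_lg.get(lg, 0.0)
            if tau is None:
                raise ValueError(f"no tau configured for linkage group {lg}")
            SegregationParams(tau, beta)  # range validation
        for spec in self.loci:
            validate_maternal(spec.maternal, spec.genotype)

    def loci_by_lg(self) -> Dict[int, List[LocusSpec]]:
        grouped: Dict[int, List[LocusSpec]] = {}
        for spec in self.loci:
            grouped.setdefault(spec.genotype.linkage_group, []).append(spec)
        for lg in grouped:
            grouped[lg].sort(key=lambda s: (s.position, s.genotype.locus_name))
        return grouped


@dataclass
class SimulatedGamete:
    gamete_id: str
    classes: Dict[str, GameteClass]
    modes: Dict[int, str]  # lg -> disomic | chromosomal | double_reduction
    recombinant: Dict[int, bool]


def simulate_gametes_single_locus(
    genotype: TetraploidGenotype,
    scenario: PairingScenario,
    params: SegregationParams,
    n: int,
    seed: int,
) -> LocusCounts:
    """n independent draws from the single-locus class distribution."""
    if n < 1:
        raise ValueError("n must be positive")
    dist = gamete_class_distribution(genotype, scenario, params)
    classes = sorted(dist)
    probs = np.array([dist[c] for c in classes])
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs / probs.sum())
    return LocusCounts(
        genotype.locus_name,
        {cls: int(k) for cls, k in zip(classes, draws) if k > 0},
    )


def _copy_order(genotype: TetraploidGenotype) -> List:
    """Chromosome identities in fixed order M1, M2, P1, P2."""
    return sorted(genotype.copies, key=lambda c: (c.origin, c.copy_index))


def _transmit_chromosomal(
    rng: np.random.Generator,
    specs: Sequence[LocusSpec],
    crossover_prob: float,
) -> List[Tuple[int, int]]:
    """Random-pairing transmission: per locus, the two transmitted chromosome
    ids (0,1 = M copies; 2,3 = P copies), with intergeneric crossovers."""
    partition = _PARTITIONS[rng.integers(3)]
    current = [pair[rng.integers(2)] for pair in partition]
    out = []
    origins = (0, 0, 1, 1)
    for idx, _spec in enumerate(specs):
        if idx > 0 and crossover_prob > 0:
            for s, pair in enumerate(partition):
                if origins[pair[0]] != origins[pair[1]]:
                    if rng.random() < crossover_prob:
                        current[s] = pair[1] if current[s] == pair[0] else pair[0]
        out.append((current[0], current[1]))
    return out


def simulate_multilocus(
    config: SimulationConfig,
) -> Tuple[List[SimulatedGamete], "GameteMatrix"]:
    """Simulate multilocus gametes; returns the gametes and their matrix.

    One meiotic mode is drawn per gamete and linkage group.  Child random
    streams are derived from the master seed with a (gamete, linkage-group)
    counter, so extending the marker set of one group does not perturb the
    draws of another.
    """
    from .transmission import GameteMatrix  # local import avoids a cycle

    grouped = config.loci_by_lg()
    lgs = sorted(grouped)
    width = len(str(config.n_gametes))
    gametes: List[SimulatedGamete] = []
    for g in range(config.n_gametes):
        classes: Dict[str, GameteClass] = {}
        modes: Dict[int, str] = {}
        recomb: Dict[int, bool] = {}
        for lg_idx, lg in enumerate(lgs):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(g, lg_idx))
            )
            specs = grouped[lg]
            tau = config.tau_by_lg[lg]
            beta = config.beta_by_lg.get(lg, 0.0)
            u = rng.random()
            if u < 1.0 - tau:
                mode = "disomic"
                mi, pi = int(rng.integers(2)), int(rng.integers(2))
                transmitted = [(mi, 2 + pi)] * len(specs)
            elif u < 1.0 - tau * beta:
                mode = "chromosomal"
                transmitted = _transmit_chromosomal(
                    rng, specs, config.crossover_prob
                )
            else:
                mode = "double_reduction"
                transmitted = _transmit_chromosomal(
                    rng, specs, config.crossover_prob
                )
                focal_name = (config.dr_focal or {}).get(
                    lg, specs[0].genotype.locus_name
                )
                dr_chrom = int(rng.integers(4))
                for idx, spec in enumerate(specs):
                    if spec.genotype.locus_name == focal_name:
                        transmitted[idx] = (dr_chrom, dr_chrom)
            modes[lg] = mode

            dosages = set()
            for spec, (i, j) in zip(specs, transmitted):
                order = _copy_order(spec.genotype)
                cls = gamete_class(order[i].allele, order[j].allele)
                classes[spec.genotype.locus_name] = cls
                if spec.genotype.is_fully_differentiating:
                    dosages.add((i < 2) + (j < 2))  # mandarin-copy dosage
            recomb[lg] = len(dosages) > 1
        gametes.append(
            SimulatedGamete(f"g{g + 1:0{width}d}", classes, modes, recomb)
        )

    loci = [spec.genotype.locus_name for spec in config.loci]
    grid = pd.DataFrame(
        [[gam.classes[l] for l in loci] for gam in gametes],
        index=[gam.gamete_id for gam in gametes],
        columns=loci,
        dtype=object,
    )
    origin_maps = {
        spec.genotype.locus_name: spec.genotype.origin_map for spec in config.loci
    }
    lg_map = {
        spec.genotype.locus_name: spec.genotype.linkage_group
        for spec in config.loci
    }
    return gametes, GameteMatrix(grid, origin_maps, lg_map)


def fuse_with_maternal(
    gametes: Sequence[SimulatedGamete],
    maternal: Mapping[str, MaternalGenotype],
    seed: int,
) -> pd.DataFrame:
    """Fuse each gamete with one maternal allele per locus.

    Returns the long-format triploid genotype table (columns ``progeny_id``,
    ``locus``, ``allele``, ``dosage``); null alleles do not amplify and are
    dropped from the visible dosages.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gam in gametes:
        for locus, cls in sorted(gam.classes.items()):
            mat = maternal[locus]
            het_overlap = (
                not mat.is_homozygous and set(mat.alleles) & set(cls)
            )
            if het_overlap:
                raise ValueError(
                    f"locus {locus}: heterozygous maternal genotype overlaps "
                    "the gamete alleles; progeny would be uninterpretable"
                )
            m_allele = mat.alleles[int(rng.integers(2))]
            dosages = Counter([m_allele])
            for a in cls:
                if a != NULL_ALLELE:
                    dosages[a] += 1
            for allele in sorted(dosages):
                rows.append(
                    {
                        "progeny_id": gam.gamete_id,
                        "locus": locus,
                        "allele": allele,
                        "dosage": dosages[allele],
                    }
                )
    return pd.DataFrame(rows, columns=["progeny_id", "locus", "allele", "dosage"])
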