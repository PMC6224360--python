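"""Packaged worked-example data: the citrus x poncirus somatic-hybrid study.

The tetraploid somatic hybrid "Flhorag1" (Willow-leaf mandarin + Pomeroy
poncirus protoplast fusion) was crossed as pollen parent to the diploid
Chandler pummelo, and 58 diploid pollen gametes were inferred from the
triploid progeny at 19 SSR and 9 centromeric SNP loci covering the nine
citrus linkage groups.  This module ships the published per-locus
gamete-class counts and parental constitutions, the per-linkage-group tau
means and intergeneric recombination frequencies reported alongside them,
and a :func:`study_config` builder that mirrors those conditions in the
simulator.

Gamete classes are keyed by canonical allele pairs; allele symbols follow
the published tables (per-locus labels A-D, with "0" the null allele of the
poncirus genome at mCrCIR02F12).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import pandas as pd

from .inference import MaternalGenotype
from .model import GameteClass, TetraploidGenotype, gamete_class
from .simulate import LocusSpec, SimulationConfig

__all__ = [
    "LocusRecord",
    "flhorag1_counts",
    "retained_loci",
    "LG_TAU_MEAN",
    "LG_BETA",
    "LG_RECOMBINATION_FREQ",
    "study_config",
    "progeny_tables",
]

N_GAMETES = 58

#: Per-linkage-group tau means reported for the combined SSR+SNP marker set.
LG_TAU_MEAN: Dict[int, float] = {
    1: 0.47, 2: 0.09, 3: 0.21, 4: 0.29, 5: 0.36, 6: 0.18, 7: 0.34, 8: 0.15,
    9: 0.40,
}

#: Double-reduction rates (relative to tau) detected per linkage group;
#: groups without a detected rate carry 0.
LG_BETA: Dict[int, float] = {
    1: 0.0, 2: 0.07, 3: 0.05, 4: 0.04, 5: 0.0, 6: 0.0, 7: 0.0, 8: 0.03,
    9: 0.07,
}

#: Observed intergeneric recombinant-gamete frequencies per linkage group.
LG_RECOMBINATION_FREQ: Dict[int, float] = {
    1: 0.29, 2: 0.09, 3: 0.14, 4: 0.24, 5: 0.26, 6: 0.10, 7: 0.16, 8: 0.14,
    9: 0.26,
}


@dataclass(frozen=True)
class LocusRecord:
    """One marker of the study: constitution, counts and status flags."""

    name: str
    lg: int
    marker_type: str  # "SSR" | "SNP"
    wlm: str  # mandarin-parent diploid genotype, e.g. "BC"
    pon: str  # poncirus-parent diploid genotype, e.g. "A0"
    counts: Dict[GameteClass, int]
    distorted: bool = False  # flagged and excluded in the source analysis

    @property
    def genotype(self) -> TetraploidGenotype:
        return TetraploidGenotype.from_parents(self.name, self.wlm, self.pon, self.lg)

    @property
    def maternal(self) -> MaternalGenotype:
        # The pummelo seed parent is fully differentiated from both fusion
        # parents at the SSRs; at the SNPs it is homozygous for the mandarin
        # allele (AA x AABB design).
        if self.marker_type == "SNP":
            return MaternalGenotype(self.name, ("A", "A"))
        return MaternalGenotype(self.name, ("E", "F"))


def _counts(raw: Dict[str, int]) -> Dict[GameteClass, int]:
    return {gamete_class(k[0], k[1]): v for k, v in raw.items() if v > 0}


_SSR_ROWS: List[Tuple[str, int, str, str, Dict[str, int], bool]] = [
    ("CiBE5055", 1, "BC", "AA", {"AA": 5, "AB": 22, "AC": 28, "BC": 3}, False),
    ("MEST431", 1, "BB", "AA", {"AA": 5, "AB": 46, "BB": 7}, False),
    ("mCrCIR02D09", 2, "AB", "CC",
     {"AA": 1, "AC": 25, "BB": 1, "CC": 1, "BC": 30}, False),
    ("MEST46", 2, "BB", "AA", {"AA": 2, "AB": 56}, False),
    ("mCrCIR02G12", 3, "CC", "AB",
     {"AA": 2, "AB": 3, "AC": 25, "BB": 1, "BC": 27}, False),
    ("mCrCIR02D04b", 4, "AA", "BC",
     {"AA": 5, "AB": 28, "AC": 24, "BC": 1}, False),
    ("mCrCIR03D12a", 4, "AA", "BC",
     {"AA": 1, "AB": 28, "AC": 24, "BB": 1, "CC": 1, "BC": 3}, False),
    ("mCrCIR07D06", 4, "AB", "CC", {"AC": 26, "CC": 6, "BC": 26}, False),
    ("mCrCIR03F05", 4, "BB", "AC",
     {"AA": 2, "AB": 27, "AC": 8, "CC": 4, "BC": 17}, True),
    ("mCrCIR01F08a", 5, "BB", "AA", {"AA": 3, "AB": 50, "BB": 5}, False),
    ("mCrCIR07E12", 5, "AC", "BB",
     {"AB": 26, "AC": 5, "BB": 2, "BC": 25}, False),
    ("mCrCIR02F12", 6, "AB", "C0",
     {"AB": 3, "AC": 14, "A0": 10, "BC": 21, "B0": 9, "C0": 1}, False),
    ("mCrCIR02D03", 7, "AB", "AC",
     {"AA": 1, "AB": 5, "AC": 28, "BB": 1, "CC": 1, "BC": 22}, True),
    ("mCrCIR07E05", 7, "BB", "AA", {"AA": 4, "AB": 51, "BB": 3}, False),
    ("mCrCIR02A09", 8, "CC", "AB",
     {"AA": 1, "AB": 1, "AC": 28, "CC": 2, "BC": 26}, False),
    ("mCrCIR07B05", 8, "BB", "AA", {"AA": 1, "AB": 55, "BB": 2}, False),
    ("mCrCIR02G02", 8, "AB", "CD",
     {"AB": 2, "AC": 23, "AD": 7, "BC": 13, "BD": 12, "CD": 1}, False),
    ("mCrCIR07C09", 9, "AC", "BC",
     {"AA": 1, "AB": 20, "AC": 7, "BB": 1, "CC": 11, "BC": 18}, True),
    ("mCrCIR02B07", 9, "AC", "BB",
     {"AB": 25, "AC": 3, "BB": 5, "CC": 2, "BC": 23}, False),
]

_SNP_ROWS: List[Tuple[str, int, Tuple[int, int, int]]] = [
    ("P1_16582061", 1, (5, 50, 3)),
    ("P2_19903193", 2, (1, 56, 1)),
    ("P3_16287238", 3, (3, 54, 1)),
    ("P4_9505439", 4, (4, 52, 2)),
    ("P5_20142568", 5, (2, 52, 4)),
    ("P6_3130249", 6, (2, 55, 1)),
    ("P7_15458045", 7, (2, 52, 4)),
    ("P8_16631925", 8, (1, 55, 2)),
    ("P9_12062066", 9, (5, 50, 3)),
]


def flhorag1_counts() -> Dict[str, LocusRecord]:
    """All 19 SSR and 9 SNP loci with their published gamete-class counts.

    Every locus totals 58 gametes; the three segregation-distorted SSRs are
    flagged ``distorted`` (they were excluded from model fitting).
    """
    records: Dict[str, LocusRecord] = {}
    for name, lg, wlm, pon, raw, distorted in _SSR_ROWS:
        records[name] = LocusRecord(name, lg, "SSR", wlm, pon, _counts(raw), distorted)
    for name, lg, (n_aa, n_ab, n_bb) in _SNP_ROWS:
        records[name] = LocusRecord(
            name, lg, "SNP", "AA", "BB",
            _counts({"AA": n_aa, "AB": n_ab, "BB": n_bb}), False,
        )
    for rec in records.values():
        assert sum(rec.counts.values()) == N_GAMETES
    return records


def retained_loci() -> Dict[str, LocusRecord]:
    """The 25 loci kept after the segregation-distortion screen."""
    return {k: r for k, r in flhorag1_counts().items() if not r.distorted}


def study_config(
    n_gametes: int = N_GAMETES,
    seed: int = 0,
    crossover_prob: float = 0.25,
) -> SimulationConfig:
    """Simulator configuration mirroring the study conditions.

    25 retained loci across nine linkage groups, per-group tau and beta set
    to the reported means, 58 gametes.  ``crossover_prob`` is a free
    parameter of the generative model (the study reports per-group
    recombinant frequencies, not per-interval rates); the default yields
    recombinant-gamete frequencies in the observed 0.1-0.3 range.
    """
    specs = []
    for rec in retained_loci().values():
        specs.append(
            LocusSpec(
                genotype=rec.genotype,
                maternal=rec.maternal,
                position=0 if rec.marker_type == "SNP" else 1,
            )
        )
    return SimulationConfig(
        loci=specs,
        tau_by_lg=dict(LG_TAU_MEAN),
        beta_by_lg=dict(LG_BETA),
        crossover_prob=crossover_prob,
        n_gametes=n_gametes,
        seed=seed,
    )


def progeny_tables(seed: int = 0) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstructed long-format progeny and parent tables for the study.

    Expands the published per-locus counts into 58 pseudo-progeny triploid
    calls by fusing each gamete class with a maternal allele.  The
    assignment of gamete classes to progeny identifiers is deterministic and
    arbitrary, so per-locus analyses reproduce the published tables exactly
    while multilocus patterns (recombination, dissimilarity) are synthetic.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    records = flhorag1_counts()
    geno_rows = []
    parent_rows = []
    for rec in records.values():
        mat = rec.maternal
        parent_rows.append(
            {"locus": rec.name, "linkage_group": rec.lg, "parent": "WLM",
             "alleles": "/".join(rec.wlm)}
        )
        parent_rows.append(
            {"locus": rec.name, "linkage_group": rec.lg, "parent": "PON",
             "alleles": "/".join(rec.pon)}
        )
        parent_rows.append(
            {"locus": rec.name, "linkage_group": rec.lg, "parent": "CHA",
             "alleles": "/".join(mat.alleles)}
        )
        gametes: List[GameteClass] = []
        for cls in sorted(rec.counts):
            gametes.extend([cls] * rec.counts[cls])
        for idx, cls in enumerate(gametes):
            pid = f"g{idx + 1:02d}"
            from collections import Counter

            dosages = Counter([mat.alleles[int(rng.integers(2))]])
            for a in cls:
                if a != "0":
                    dosages[a] += 1
            for allele in sorted(dosages):
                geno_rows.append(
                    {"progeny_id": pid, "locus": rec.name, "allele": allele,
                     "dosage": dosages[allele]}
                )
    genotypes = pd.DataFrame(
        geno_rows, columns=["progeny_id", "locus", "allele", "dosage"]
    )
    parents = pd.DataFrame(
        parent_rows, columns=["locus", "linkage_group", "parent", "alleles"]
    )
    return genotypes, parents
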