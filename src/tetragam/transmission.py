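"""Population-level summaries over the inferred gamete matrix.

Covers heterozygosity transmission (how often a gamete unites alleles from
the two ancestral genera, or two distinct alleles of one genus), per
linkage-group aggregation of the fitted tau values, detection of
intergeneric recombinant gametes from multilocus genus-dosage patterns, and
simple-matching dissimilarities between gametes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .inference import GameteCall, LocusCounts, tabulate_gametes
from .model import GameteClass, TetraploidGenotype

__all__ = [
    "INTERGENERIC_HET",
    "INTRAGENERIC_HET",
    "HOMOZYGOUS",
    "GameteMatrix",
    "TransmissionSummary",
    "LinkageGroupSummary",
    "CorrelationResult",
    "DissimilarityMatrix",
    "classify_gamete_locus",
    "heterozygosity_from_counts",
    "heterozygosity_summary",
    "detect_recombinants",
    "simple_matching_dissimilarity",
    "aggregate_by_lg",
    "correlate",
]

INTERGENERIC_HET = "intergeneric_het"
INTRAGENERIC_HET = "intrageneric_het"
HOMOZYGOUS = "homozygous"


@dataclass
class GameteMatrix:
    """Gamete x locus grid of gamete classes with per-locus annotations.

    ``data`` holds one row per gamete and one column per locus; cells are
    canonical gamete classes (2-tuples) or ``None`` for missing calls.
    ``origin_maps`` gives, per locus, the genome label (M or P) of every
    allele; ``lg_map`` assigns each locus to a linkage group.
    """

    data: pd.DataFrame
    origin_maps: Dict[str, Dict[str, str]]
    lg_map: Dict[str, int]

    def __post_init__(self) -> None:
        for locus in self.data.columns:
            if locus not in self.origin_maps:
                raise ValueError(f"no origin map for locus {locus}")
            omap = self.origin_maps[locus]
            for cell in self.data[locus]:
                if cell is None:
                    continue
                for allele in cell:
                    if allele not in omap:
                        raise ValueError(
                            f"allele {allele!r} at {locus} missing from origin map"
                        )

    @classmethod
    def from_calls(
        cls,
        calls: Sequence[GameteCall],
        genotypes: Mapping[str, TetraploidGenotype],
        lg_map: Optional[Mapping[str, int]] = None,
    ) -> "GameteMatrix":
        loci = sorted({c.locus_name for c in calls})
        ids = sorted({c.progeny_id for c in calls})
        grid = pd.DataFrame(None, index=ids, columns=loci, dtype=object)
        for c in calls:
            if c.status == "ok" and c.gamete is not None:
                grid.at[c.progeny_id, c.locus_name] = c.gamete
        origin_maps = {l: genotypes[l].origin_map for l in loci}
        lgs = dict(lg_map) if lg_map else {
            l: genotypes[l].linkage_group for l in loci
        }
        return cls(grid, origin_maps, lgs)

    def loci_for_lg(self, lg: int) -> List[str]:
        return [l for l in self.data.columns if self.lg_map.get(l) == lg]

    def counts(self) -> Dict[str, LocusCounts]:
        out = {}
        for locus in self.data.columns:
            tally: Dict[GameteClass, int] = {}
            for cell in self.data[locus]:
                if cell is not None:
                    tally[cell] = tally.get(cell, 0) + 1
            out[locus] = LocusCounts(locus, tally)
        return out


@dataclass
class TransmissionSummary:
    """Per-locus and overall heterozygosity-transmission percentages."""

    per_locus: pd.DataFrame
    overall_intergeneric_pct: float
    overall_intrageneric_pct: float
    overall_homozygous_pct: float
    n_observations: int


@dataclass
class LinkageGroupSummary:
    lg: int
    markers: List[str]
    tau_mean: float
    tau_sd: float
    recombinant_count: Optional[int] = None
    recombination_frequency: Optional[float] = None


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    n: int


@dataclass
class DissimilarityMatrix:
    values: pd.DataFrame
    mode: str  # "all-alleles" | "genus-recoded"


def classify_gamete_locus(
    gamete: GameteClass, origin_map: Mapping[str, str]
) -> str:
    """Category of a gamete at one locus.

    * intergeneric_het: one allele from each genome;
    * intrageneric_het: two distinct alleles (the null included) of one genome;
    * homozygous: two copies of the same allele.
    """
    a, b = gamete
    try:
        oa, ob = origin_map[a], origin_map[b]
    except KeyError as err:
        raise ValueError(f"allele {err.args[0]!r} not in origin map") from None
    if oa != ob:
        return INTERGENERIC_HET
    if a != b:
        return INTRAGENERIC_HET
    return HOMOZYGOUS


def heterozygosity_from_counts(
    counts: Mapping[str, LocusCounts],
    origin_maps: Mapping[str, Mapping[str, str]],
) -> TransmissionSummary:
    """Transmission summary from per-locus gamete-class counts.

    The overall intergeneric average pools gamete-locus observations, i.e.
    it is total intergeneric-het observations over total observations.
    """
    rows = []
    totals = Counter()
    grand = 0
    for locus, lc in counts.items():
        cat = Counter()
        for cls, k in lc.counts.items():
            cat[classify_gamete_locus(tuple(cls), origin_maps[locus])] += k
        n = lc.n
        rows.append(
            {
                "locus": locus,
                "n": n,
                "intergeneric_het": cat[INTERGENERIC_HET],
                "intrageneric_het": cat[INTRAGENERIC_HET],
                "homozygous": cat[HOMOZYGOUS],
                "intergeneric_het_pct": 100.0 * cat[INTERGENERIC_HET] / n if n else math.nan,
                "intrageneric_het_pct": 100.0 * cat[INTRAGENERIC_HET] / n if n else math.nan,
                "homozygous_pct": 100.0 * cat[HOMOZYGOUS] / n if n else math.nan,
            }
        )
        totals.update(cat)
        grand += n
    if grand == 0:
        raise ValueError("no gamete observations")
    per_locus = pd.DataFrame(rows).set_index("locus")
    return TransmissionSummary(
        per_locus=per_locus,
        overall_intergeneric_pct=100.0 * totals[INTERGENERIC_HET] / grand,
        overall_intrageneric_pct=100.0 * totals[INTRAGENERIC_HET] / grand,
        overall_homozygous_pct=100.0 * totals[HOMOZYGOUS] / grand,
        n_observations=grand,
    )


def heterozygosity_summary(matrix: GameteMatrix) -> TransmissionSummary:
    """Transmission summary over a gamete matrix (complete cases per locus)."""
    return heterozygosity_from_counts(matrix.counts(), matrix.origin_maps)


def _m_dosage(gamete: GameteClass, origin_map: Mapping[str, str]) -> int:
    return sum(1 for a in gamete if origin_map[a] == "M")


def detect_recombinants(matrix: GameteMatrix, lg: int) -> Tuple[int, float]:
    """Count gametes whose genus dosage varies across the loci of one LG.

    A gamete built from two genus-constant haplotypes has the same
    mandarin-allele dosage (0, 1 or 2) at every locus of the linkage group;
    any dosage change therefore marks an intergeneric recombination.  Only
    fully genus-differentiating loci are informative; gametes scored at
    fewer than two non-missing informative loci are skipped.
    """
    loci = [
        l
        for l in matrix.loci_for_lg(lg)
        if len(set(matrix.origin_maps[l].values())) == 2
    ]
    if len(loci) < 2:
        raise ValueError(f"linkage group {lg}: fewer than two informative loci")
    recombinant = 0
    scored = 0
    for _, row in matrix.data[loci].iterrows():
        dosages = {
            _m_dosage(cell, matrix.origin_maps[l])
            for l, cell in row.items()
            if cell is not None
        }
        if len({l for l, cell in row.items() if cell is not None}) < 2:
            continue
        scored += 1
        if len(dosages) > 1:
            recombinant += 1
    if scored == 0:
        raise ValueError(f"linkage group {lg}: no gamete scored at two loci")
    return recombinant, recombinant / scored


def simple_matching_dissimilarity(
    matrix: GameteMatrix, mode: str = "all-alleles"
) -> DissimilarityMatrix:
    """Pairwise simple-matching dissimilarity between gametes.

    ``d(i,j) = 1 - (1/L_ij) sum_l m_l / 2`` where ``m_l`` is the size of the
    multiset intersection of the two gametes' allele pairs at locus ``l`` and
    ``L_ij`` the number of loci scored in both gametes.  In genus-recoded
    mode every allele is first replaced by its genome label, so only
    intergeneric structure contributes.
    """
    if mode not in ("all-alleles", "genus-recoded"):
        raise ValueError(f"unknown mode {mode!r}")
    ids = list(matrix.data.index)
    if len(ids) < 2:
        raise ValueError("dissimilarity needs at least two gametes")
    loci = list(matrix.data.columns)
    # pre-encode cells
    encoded: List[List[Optional[Tuple[str, str]]]] = []
    for gid in ids:
        row = []
        for l in loci:
            cell = matrix.data.at[gid, l]
            if cell is None:
                row.append(None)
            elif mode == "genus-recoded":
                omap = matrix.origin_maps[l]
                row.append(tuple(sorted(omap[a] for a in cell)))
            else:
                row.append(tuple(cell))
        encoded.append(row)

    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = 0
            match = 0.0
            for ci, cj in zip(encoded[i], encoded[j]):
                if ci is None or cj is None:
                    continue
                shared += 1
                inter = Counter(ci) & Counter(cj)
                match += sum(inter.values()) / 2.0
            if shared == 0:
                raise ValueError(
                    f"gametes {ids[i]} and {ids[j]} share no scored locus"
                )
            out[i, j] = out[j, i] = 1.0 - match / shared
    return DissimilarityMatrix(
        values=pd.DataFrame(out, index=ids, columns=ids), mode=mode
    )


def aggregate_by_lg(
    fits: Sequence, lg_map: Mapping[str, int]
) -> List[LinkageGroupSummary]:
    """Mean and sample standard deviation (n-1) of tau_hat per linkage group."""
    by_lg: Dict[int, List] = {}
    for fit in fits:
        if fit.locus_name not in lg_map:
            raise ValueError(f"locus {fit.locus_name} has no linkage-group mapping")
        by_lg.setdefault(lg_map[fit.locus_name], []).append(fit)
    out = []
    for lg in sorted(by_lg):
        taus = np.array([f.tau_hat for f in by_lg[lg]], dtype=float)
        sd = float(np.std(taus, ddof=1)) if len(taus) > 1 else 0.0
        out.append(
            LinkageGroupSummary(
                lg=lg,
                markers=[f.locus_name for f in by_lg[lg]],
                tau_mean=float(np.mean(taus)),
                tau_sd=sd,
            )
        )
    return out


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation and its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    r = float(pearsonr(x, y).statistic)
    return CorrelationResult(r=r, r_squared=r * r, n=len(x))
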