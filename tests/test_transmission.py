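"""Heterozygosity transmission, recombination, dissimilarity, aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetragam import (
    LocusCounts,
    aggregate_by_lg,
    classify_gamete_locus,
    correlate,
    detect_recombinants,
    heterozygosity_from_counts,
    heterozygosity_summary,
    simple_matching_dissimilarity,
)
from tetragam.datasets import (
    LG_RECOMBINATION_FREQ,
    LG_TAU_MEAN,
    retained_loci,
    study_config,
)
from tetragam.simulate import simulate_multilocus
from tetragam.transmission import GameteMatrix

from .conftest import locus_counts


@pytest.mark.parametrize(
    "gamete, expected",
    [
        (("A", "C"), "intergeneric_het"),
        (("0", "C"), "intrageneric_het"),  # null counts as an allele of its genome
        (("A", "A"), "homozygous"),
    ],
)
def test_classify_gamete_locus(gamete, expected):
    omap = {"A": "M", "B": "M", "C": "P", "0": "P"}
    assert classify_gamete_locus(gamete, omap) == expected


def test_classify_unknown_allele():
    with pytest.raises(ValueError):
        classify_gamete_locus(("A", "Z"), {"A": "M"})


def small_matrix(cells, omap, lg=1):
    loci = sorted({l for row in cells.values() for l in row})
    data = pd.DataFrame(
        [[cells[g].get(l) for l in loci] for g in sorted(cells)],
        index=sorted(cells), columns=loci, dtype=object,
    )
    return GameteMatrix(data, {l: dict(omap) for l in loci}, {l: lg for l in loci})


class TestHeterozygositySummary:
    def test_study_per_locus_percentages(self, retained_records):
        counts = {n: locus_counts(r) for n, r in retained_records.items()}
        omaps = {n: r.genotype.origin_map for n, r in retained_records.items()}
        summ = heterozygosity_from_counts(counts, omaps)
        # SNP locus on chromosome 2: 56/58 intergeneric
        p2 = summ.per_locus.loc["P2_19903193", "intergeneric_het_pct"]
        assert round(p2) == 97
        # SSR with 5 intragenerically heterozygous gametes
        e12 = summ.per_locus.loc["mCrCIR07E12", "intrageneric_het_pct"]
        assert round(e12) == 9
        # category counts partition n at every locus
        per = summ.per_locus
        assert (
            per[["intergeneric_het", "intrageneric_het", "homozygous"]].sum(axis=1)
            == per["n"]
        ).all()

    def test_study_overall_average(self, retained_records):
        counts = {n: locus_counts(r) for n, r in retained_records.items()}
        omaps = {n: r.genotype.origin_map for n, r in retained_records.items()}
        summ = heterozygosity_from_counts(counts, omaps)
        assert summ.n_observations == 25 * 58
        assert summ.overall_intergeneric_pct == pytest.approx(
            100 * 1309 / 1450, abs=1e-9
        )

    def test_all_homozygous_matrix(self):
        omap = {"A": "M", "B": "P"}
        m = small_matrix(
            {"g1": {"L1": ("A", "A")}, "g2": {"L1": ("B", "B")}}, omap
        )
        summ = heterozygosity_summary(m)
        assert summ.overall_homozygous_pct == 100.0
        assert summ.overall_intergeneric_pct == 0.0


class TestRecombinants:
    def test_dosage_change_marks_recombinant(self):
        omap = {"A": "M", "B": "P"}
        m = small_matrix(
            {
                "g1": {"L1": ("A", "A"), "L2": ("A", "B")},  # dosage 2 -> 1
                "g2": {"L1": ("A", "B"), "L2": ("A", "B")},  # constant 1
                "g3": {"L1": ("B", "B"), "L2": ("B", "B")},  # constant 0
            },
            omap,
        )
        count, freq = detect_recombinants(m, 1)
        assert count == 1 and freq == pytest.approx(1 / 3)

    def test_requires_two_informative_loci(self):
        omap = {"A": "M", "B": "P"}
        m = small_matrix({"g1": {"L1": ("A", "B")}}, omap)
        with pytest.raises(ValueError):
            detect_recombinants(m, 1)

    def test_no_recombinants_without_crossover_or_tetrasomy(self):
        cfg = study_config(n_gametes=120, seed=5, crossover_prob=0.0)
        cfg.tau_by_lg = {lg: 0.0 for lg in cfg.tau_by_lg}
        cfg.beta_by_lg = {lg: 0.0 for lg in cfg.beta_by_lg}
        _, matrix = simulate_multilocus(cfg)
        for lg in range(1, 10):
            count, freq = detect_recombinants(matrix, lg)
            assert count == 0 and freq == 0.0

    def test_frequency_monotone_in_crossover_probability(self):
        means = []
        for xp in (0.0, 0.2, 0.5):
            cfg = study_config(n_gametes=250, seed=9, crossover_prob=xp)
            _, matrix = simulate_multilocus(cfg)
            freqs = [detect_recombinants(matrix, lg)[1] for lg in range(1, 10)]
            means.append(float(np.mean(freqs)))
        assert means[0] <= means[1] <= means[2]


class TestDissimilarity:
    omap = {"A": "M", "B": "M", "C": "P", "D": "P"}

    def test_identical_and_disjoint_gametes(self):
        m = small_matrix(
            {
                "g1": {"L1": ("A", "C"), "L2": ("A", "C")},
                "g2": {"L1": ("A", "C"), "L2": ("A", "C")},
                "g3": {"L1": ("B", "D"), "L2": ("B", "D")},
            },
            self.omap,
        )
        dm = simple_matching_dissimilarity(m).values
        assert dm.loc["g1", "g2"] == 0.0
        assert dm.loc["g1", "g3"] == 1.0
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_half_match_single_locus(self):
        m = small_matrix(
            {"g1": {"L1": ("A", "B")}, "g2": {"L1": ("A", "C")}}, self.omap
        )
        dm = simple_matching_dissimilarity(m).values
        assert dm.loc["g1", "g2"] == pytest.approx(0.5)

    def test_genus_recoding_concentrates_at_low_dissimilarity(self):
        """Preferential pairing makes genus-level gamete diversity much lower
        than all-allele diversity (the published distribution contrast)."""
        cfg = study_config(n_gametes=58, seed=21)
        _, matrix = simulate_multilocus(cfg)
        d_all = simple_matching_dissimilarity(matrix, "all-alleles")
        d_gen = simple_matching_dissimilarity(matrix, "genus-recoded")
        iu = np.triu_indices(len(matrix.data), k=1)
        assert d_gen.values.values[iu].mean() < d_all.values.values[iu].mean()

    def test_pairwise_complete_loci(self):
        m = small_matrix(
            {"g1": {"L1": ("A", "B"), "L2": None}, "g2": {"L1": ("A", "B"), "L2": ("A", "C")}},
            self.omap,
        )
        dm = simple_matching_dissimilarity(m).values
        assert dm.loc["g1", "g2"] == 0.0  # only L1 shared, full match


class TestAggregation:
    class _F:
        def __init__(self, locus, tau):
            self.locus_name = locus
            self.tau_hat = tau

    @pytest.mark.parametrize(
        "taus, mean, sd",
        [
            ((0.21, 0.21), 0.21, 0.0),
            ((0.30,), 0.30, 0.0),
            ((0.07, 0.10, 0.11), 0.0933, 0.0208),
        ],
    )
    def test_mean_and_sample_sd(self, taus, mean, sd):
        fits = [self._F(f"m{i}", t) for i, t in enumerate(taus)]
        out = aggregate_by_lg(fits, {f"m{i}": 3 for i in range(len(taus))})
        assert len(out) == 1
        assert out[0].tau_mean == pytest.approx(mean, abs=5e-3)
        assert out[0].tau_sd == pytest.approx(sd, abs=5e-3)
        assert min(taus) <= out[0].tau_mean <= max(taus)

    def test_unmapped_locus_rejected(self):
        with pytest.raises(ValueError):
            aggregate_by_lg([self._F("m", 0.1)], {})


class TestCorrelate:
    def test_published_lg_values(self):
        lgs = sorted(LG_TAU_MEAN)
        cr = correlate(
            [LG_TAU_MEAN[l] for l in lgs], [LG_RECOMBINATION_FREQ[l] for l in lgs]
        )
        assert cr.n == 9
        assert round(cr.r_squared, 2) == 0.82
        assert cr.r_squared == pytest.approx(cr.r**2)

    def test_perfect_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        cr = correlate(x, [2 * v + 1 for v in x])
        assert cr.r_squared == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
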