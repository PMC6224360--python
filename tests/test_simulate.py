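"""Meiosis simulator: marginals, determinism, fusion, packaged dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tetragam import (
    MaternalGenotype,
    SegregationParams,
    TetraploidGenotype,
    fit_duplex,
    fit_locus,
    infer_gamete,
    tabulate_gametes,
)
from tetragam.datasets import (
    LG_BETA,
    LG_TAU_MEAN,
    N_GAMETES,
    flhorag1_counts,
    retained_loci,
    study_config,
)
from tetragam.io import read_genotype_table, write_genotype_table
from tetragam.model import gamete_class_distribution, homologous_scenario
from tetragam.simulate import (
    LocusSpec,
    SimulationConfig,
    fuse_with_maternal,
    simulate_gametes_single_locus,
    simulate_multilocus,
)


def geno(m, p, name="L", lg=1):
    return TetraploidGenotype.from_parents(name, m, p, lg)


class TestSingleLocus:
    def test_bit_reproducible(self):
        g = geno("AB", "CC")
        s = homologous_scenario(g)
        params = SegregationParams(0.4, 0.1)
        a = simulate_gametes_single_locus(g, s, params, 500, seed=3)
        b = simulate_gametes_single_locus(g, s, params, 500, seed=3)
        assert a.counts == b.counts

    def test_tau_zero_only_disomic_classes(self):
        g = geno("AB", "CD")
        s = homologous_scenario(g)
        counts = simulate_gametes_single_locus(
            g, s, SegregationParams(0.0, 0.0), 2000, seed=1
        )
        assert set(counts.counts) <= {("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")}

    def test_duplex_estimate_within_binomial_envelope(self):
        g = geno("AA", "BB")
        counts = simulate_gametes_single_locus(
            g, homologous_scenario(g), SegregationParams(0.42, 0.0), 58, seed=17
        )
        f = fit_duplex(counts, g)
        assert 0.15 <= f.tau_hat <= 0.75

    @pytest.mark.parametrize("seed", [11, 22, 33])
    def test_marginals_converge_to_model(self, seed):
        g = geno("AB", "CC")
        s = homologous_scenario(g)
        params = SegregationParams(0.5, 0.1)
        counts = simulate_gametes_single_locus(g, s, params, 100_000, seed=seed)
        dist = gamete_class_distribution(g, s, params)
        for cls, p in dist.items():
            assert abs(counts.counts.get(cls, 0) / 100_000 - p) < 0.005


class TestMultilocus:
    def test_deterministic_and_stable_under_extra_groups(self):
        cfg = study_config(n_gametes=40, seed=8)
        g1, m1 = simulate_multilocus(cfg)
        g2, m2 = simulate_multilocus(cfg)
        assert m1.data.equals(m2.data)
        assert [g.modes for g in g1] == [g.modes for g in g2]

    def test_marginals_match_mixture(self):
        """Large-n single-group check: the focal locus reproduces the full
        (tau, beta) mixture, non-focal loci the beta = 0 marginal."""
        specs = [
            LocusSpec(geno("AB", "CC", "focal", 1), MaternalGenotype("focal", ("E", "F")), 0),
            LocusSpec(geno("AA", "BB", "other", 1), MaternalGenotype("other", ("E", "F")), 1),
        ]
        cfg = SimulationConfig(
            loci=specs, tau_by_lg={1: 0.4}, beta_by_lg={1: 0.15},
            crossover_prob=0.0, n_gametes=100_000, seed=2,
        )
        _, matrix = simulate_multilocus(cfg)
        counts = matrix.counts()
        n = cfg.n_gametes
        g_f = specs[0].genotype
        dist_f = gamete_class_distribution(
            g_f, homologous_scenario(g_f), SegregationParams(0.4, 0.15)
        )
        for cls, p in dist_f.items():
            assert abs(counts["focal"].counts.get(cls, 0) / n - p) < 0.005
        g_o = specs[1].genotype
        dist_o = gamete_class_distribution(
            g_o, homologous_scenario(g_o), SegregationParams(0.4, 0.0)
        )
        for cls, p in dist_o.items():
            assert abs(counts["other"].counts.get(cls, 0) / n - p) < 0.005

    def test_modes_drawn_with_configured_rates(self):
        cfg = study_config(n_gametes=3000, seed=4)
        gametes, _ = simulate_multilocus(cfg)
        frac_dis = np.mean([g.modes[2] == "disomic" for g in gametes])
        assert abs(frac_dis - (1 - LG_TAU_MEAN[2])) < 0.03

    def test_study_conditions_recover_lg_tau_with_small_n_noise(self):
        """At n = 58 the duplex estimate is noisy but centred: over 40 seeded
        replicates the SNP-locus tau_hat covers the configured value."""
        hits = 0
        for seed in range(40):
            cfg = study_config(n_gametes=N_GAMETES, seed=1000 + seed)
            _, matrix = simulate_multilocus(cfg)
            counts = matrix.counts()["P4_9505439"]
            f = fit_duplex(counts)
            if abs(f.tau_hat - LG_TAU_MEAN[4]) <= 0.25:
                hits += 1
        assert hits >= 36  # binomial slack on the +-0.25 coverage

    def test_pipeline_recovers_scenario_and_tau_at_moderate_n(self):
        """simulate -> fuse -> infer -> fit selects the homologous scenario
        in nearly all replicates at tau <= 0.3 and n >= 500."""
        g = geno("AB", "CC", "L", 1)
        mat = MaternalGenotype("L", ("E", "F"))
        spec = LocusSpec(g, mat, 0)
        homologous_hits = 0
        reps = 40
        for seed in range(reps):
            cfg = SimulationConfig(
                loci=[spec], tau_by_lg={1: 0.25}, beta_by_lg={1: 0.0},
                n_gametes=500, seed=seed,
            )
            gametes, _ = simulate_multilocus(cfg)
            progeny = fuse_with_maternal(gametes, {"L": mat}, seed=seed + 7)
            calls = {}
            for row in progeny.itertuples(index=False):
                calls.setdefault(row.progeny_id, {})[row.allele] = row.dosage
            from tetragam import TriploidCall

            inferred = [
                infer_gamete(TriploidCall(pid, "L", dos), mat)
                for pid, dos in calls.items()
            ]
            counts = tabulate_gametes(inferred)["L"]
            f = fit_locus(counts, g)
            if f.scenario.is_homologous:
                homologous_hits += 1
        assert homologous_hits >= int(0.95 * reps)


class TestFusion:
    def test_roundtrip_recovers_every_gamete(self, tmp_path):
        cfg = study_config(n_gametes=60, seed=13)
        gametes, _ = simulate_multilocus(cfg)
        maternal = {s.genotype.locus_name: s.maternal for s in cfg.loci}
        genos = {s.genotype.locus_name: s.genotype for s in cfg.loci}
        progeny = fuse_with_maternal(gametes, maternal, seed=99)
        path = tmp_path / "genotypes.tsv"
        write_genotype_table(progeny, path)
        allowed = {l: min(2, g.alleles.count("0")) for l, g in genos.items()}
        truth = {g.gamete_id: g.classes for g in gametes}
        for call in read_genotype_table(path, allowed):
            got = infer_gamete(
                call, maternal[call.locus_name], allowed[call.locus_name]
            )
            assert got.status == "ok"
            assert got.gamete == truth[call.progeny_id][call.locus_name]

    def test_fixed_seed_reproduces_tables(self):
        cfg = study_config(n_gametes=20, seed=6)
        gametes, _ = simulate_multilocus(cfg)
        maternal = {s.genotype.locus_name: s.maternal for s in cfg.loci}
        t1 = fuse_with_maternal(gametes, maternal, seed=5)
        t2 = fuse_with_maternal(gametes, maternal, seed=5)
        assert t1.equals(t2)

    def test_heterozygous_maternal_overlap_rejected(self):
        g = geno("AB", "CC")
        spec = LocusSpec(g, MaternalGenotype("L", ("E", "F")), 0)
        cfg = SimulationConfig(
            loci=[spec], tau_by_lg={1: 0.2}, beta_by_lg={1: 0.0},
            n_gametes=10, seed=0,
        )
        gametes, _ = simulate_multilocus(cfg)
        with pytest.raises(ValueError):
            fuse_with_maternal(gametes, {"L": MaternalGenotype("L", ("A", "E"))}, 0)


class TestPackagedDataset:
    def test_fixture_totals_and_composition(self, study_records):
        assert len(study_records) == 19 + 9
        types = {r.marker_type for r in study_records.values()}
        assert types == {"SSR", "SNP"}
        for rec in study_records.values():
            assert sum(rec.counts.values()) == N_GAMETES
            observed = {a for cls in rec.counts for a in cls}
            parental = set(rec.genotype.alleles)
            assert observed <= parental
        assert sum(r.distorted for r in study_records.values()) == 3
        snps = [r for r in study_records.values() if r.marker_type == "SNP"]
        assert all(r.wlm == "AA" and r.pon == "BB" for r in snps)

    @pytest.mark.parametrize(
        "name, expected",
        [
            ("MEST46", {("A", "A"): 2, ("A", "B"): 56}),
            ("P5_20142568", {("A", "A"): 2, ("A", "B"): 52, ("B", "B"): 4}),
        ],
    )
    def test_fixture_rows(self, study_records, name, expected):
        assert study_records[name].counts == expected

    def test_retained_loci_cover_all_linkage_groups(self, retained_records):
        assert len(retained_records) == 25
        assert {r.lg for r in retained_records.values()} == set(range(1, 10))

    def test_study_config_is_valid_and_seeded(self):
        cfg = study_config(seed=42)
        assert cfg.n_gametes == N_GAMETES
        assert len(cfg.loci) == 25
        assert cfg.tau_by_lg == LG_TAU_MEAN
        assert cfg.beta_by_lg == LG_BETA
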