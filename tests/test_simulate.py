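"""Chromatid-level meiosis simulator and fluctuation-culture generator."""

from __future__ import annotations

import filecmp
import json
import math

import numpy as np
import pytest

from meiomap.simulate import (
    SimulationConfig,
    apply_gene_conversion,
    apply_viability,
    generate_study,
    preset_config,
    simulate_fluctuation,
    simulate_study_genotype,
    simulate_tetrads,
)
from meiomap.stats import (
    classify_interval,
    expected_class_probs,
    perkins_se_ci,
    segregation_tally,
    tally_intervals,
    viability_profile,
    ndj_bias_score,
    TetradClass,
)
from meiomap.tetrads import MarkerMap, read_tetrad_table
from meiomap.viability_model import DisjunctionModel


def single_interval_config(d_cm, n_tetrads, seed, conversion=0.0, **kw):
    mm = MarkerMap("X", (("A", 0.0), ("B", 50.0)))
    return SimulationConfig(
        maps={"X": mm},
        interval_cm={"X": (d_cm,)},
        n_tetrads=n_tetrads,
        seed=seed,
        conversion_rate=conversion,
        **kw,
    )


class TestSimulateTetrads:
    def test_zero_distance_all_pd(self):
        tets, _ = simulate_tetrads(single_interval_config(0.0, 50, seed=1))
        assert all(
            classify_interval(t, ("A", "B")) is TetradClass.PD for t in tets
        )

    def test_determinism_same_seed(self):
        cfg = single_interval_config(20.0, 100, seed=9)
        a, _ = simulate_tetrads(cfg)
        b, _ = simulate_tetrads(cfg)
        for ta, tb in zip(a, b):
            assert [s.alleles for s in ta.spores] == [s.alleles for s in tb.spores]

    def test_high_density_reaches_1_4_1_ratio(self):
        """At m = 10 crossovers per bivalent the PD:TT:NPD frequencies reach
        the classic no-chromatid-interference limit 1:4:1 (3 SE)."""
        n = 4000
        cfg = single_interval_config(500.0, n, seed=12)  # m = 500/50 = 10
        tets, _ = simulate_tetrads(cfg)
        counts = tally_intervals(tets, cfg.maps["X"])[("A", "B")]
        for obs, expect in [
            (counts.PD, 1 / 6), (counts.TT, 4 / 6), (counts.NPD, 1 / 6)
        ]:
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(obs / n - expect) <= 3 * se

    def test_class_frequencies_match_closed_form_at_moderate_distance(self):
        """NPD (and the other classes) at m = 0.4 match the analytic Poisson
        no-interference probabilities within 3 SE at n = 20000."""
        n = 20000
        cfg = single_interval_config(20.0, n, seed=13)
        tets, _ = simulate_tetrads(cfg)
        c = tally_intervals(tets, cfg.maps["X"])[("A", "B")]
        for obs, expect in zip(
            (c.PD, c.TT, c.NPD), expected_class_probs(0.4)
        ):
            se = math.sqrt(expect * (1 - expect) / n)
            assert abs(obs / n - expect) <= 3 * se

    def test_perkins_recovery_at_moderate_distance(self):
        """A 2000-tetrad simulation at d = 10 cM recovers d within 2 SE."""
        cfg = single_interval_config(10.0, 2000, seed=14)
        tets, _ = simulate_tetrads(cfg)
        est = perkins_se_ci(tally_intervals(tets, cfg.maps["X"])[("A", "B")])
        assert abs(est.cm - 10.0) <= 2 * est.se

    def test_manifest_crossover_counts_match_distance(self):
        cfg = single_interval_config(20.0, 5000, seed=15)
        _, manifest = simulate_tetrads(cfg)
        total = manifest.crossovers_per_interval["X"][0]
        mean = total / 5000
        # Poisson mean m = 0.4, SE = sqrt(m/n)
        assert abs(mean - 0.4) <= 3 * math.sqrt(0.4 / 5000)

    def test_invalid_config_rejected(self):
        mm = MarkerMap("X", (("A", 0.0), ("B", 50.0)))
        with pytest.raises(ValueError, match="distance per interval"):
            SimulationConfig(maps={"X": mm}, interval_cm={"X": (1.0, 2.0)})


class TestGeneConversion:
    def test_rate_zero_is_identity(self):
        cfg = single_interval_config(10.0, 50, seed=2)
        tets, _ = simulate_tetrads(cfg)
        before = [dict(s.alleles) for t in tets for s in t.spores]
        n = apply_gene_conversion(tets, 0.0, np.random.default_rng(0))
        after = [dict(s.alleles) for t in tets for s in t.spores]
        assert n == 0 and before == after

    def test_rate_one_converts_every_marker(self):
        cfg = single_interval_config(0.0, 30, seed=3)
        tets, _ = simulate_tetrads(cfg)
        apply_gene_conversion(tets, 1.0, np.random.default_rng(0))
        for t in tets:
            for marker in ("A", "B"):
                tally = segregation_tally([t], marker)
                assert tally.aberrant_3_1 + tally.aberrant_1_3 == 1

    def test_aberrant_percent_tracks_rate(self):
        """rate = 0.03 over 2000 tetrads gives ~3% aberrant segregation
        (binomial 3 SE)."""
        n = 2000
        cfg = single_interval_config(0.0, n, seed=4)
        tets, _ = simulate_tetrads(cfg)
        apply_gene_conversion(tets, 0.03, np.random.default_rng(5))
        tally = segregation_tally(tets, "A")
        se = 100 * math.sqrt(0.03 * 0.97 / n)
        assert abs(tally.percent_aberrant - 3.0) <= 3 * se


class TestApplyViability:
    def test_no_achiasmate_no_background_all_viable(self):
        cfg = single_interval_config(10.0, 40, seed=6)
        tets, manifest = simulate_tetrads(cfg)
        model = DisjunctionModel(p_disjoin=0.0, background_death=0.0)
        flags = [{"X": False}] * len(tets)
        n_ndj = apply_viability(tets, model, flags, np.random.default_rng(0))
        assert n_ndj == 0
        assert all(t.n_viable == 4 for t in tets)

    def test_forced_ndj_leaves_two_viable_and_masks_dead(self):
        cfg = single_interval_config(10.0, 40, seed=6)
        tets, _ = simulate_tetrads(cfg)
        model = DisjunctionModel(p_disjoin=0.0, background_death=0.0)
        flags = [{"X": True}] * len(tets)
        n_ndj = apply_viability(tets, model, flags, np.random.default_rng(0))
        assert n_ndj == len(tets)
        for t in tets:
            assert t.n_viable == 2
            for s in t.spores:
                if not s.viable:
                    assert set(s.alleles.values()) == {"-"}

    def test_wild_type_preset_more_viable_than_double_mutant(self):
        wt_cfg = preset_config("wild type", n_tetrads=800, seed=21)
        dm_cfg = preset_config("mlh3Δ mms4Δ", n_tetrads=800, seed=22)
        wt, _ = simulate_study_genotype(wt_cfg)
        dm, _ = simulate_study_genotype(dm_cfg)
        assert (
            viability_profile(wt).percent_viable
            > viability_profile(dm).percent_viable
        )

    def test_achiasmate_meioses_raise_ndj_bias_score(self):
        """Simulated meioses with achiasmate chromosomes at p_disjoin = 0.5
        score higher on the 4-2-0 signature than NDJ-free meioses."""
        cfg = single_interval_config(10.0, 600, seed=23)
        tets_ndj, _ = simulate_tetrads(cfg)
        tets_free, _ = simulate_tetrads(cfg)
        model_ndj = DisjunctionModel(p_disjoin=0.5, background_death=0.05)
        model_free = DisjunctionModel(p_disjoin=1.0, background_death=0.05)
        apply_viability(
            tets_ndj, model_ndj, [{"X": True}] * 600, np.random.default_rng(1)
        )
        apply_viability(
            tets_free, model_free, [{"X": True}] * 600, np.random.default_rng(2)
        )
        assert ndj_bias_score(viability_profile(tets_ndj)) > ndj_bias_score(
            viability_profile(tets_free)
        )


class TestFluctuationCultures:
    def test_zero_rate_gives_zero_counts(self):
        exp = simulate_fluctuation(0.0, 10, 10 * 2**10, 50, np.random.default_rng(0))
        assert set(exp.culture_counts) == {0}

    def test_p0_law(self):
        """Fraction of mutant-free cultures matches (1-mu)^(divisions)
        (~exp(-mu * divisions)) within 3 SE at 1000 cultures."""
        n_init, g = 16, 16
        n_fin = n_init * 2**g
        mu = 1.0 / (n_fin - n_init)  # one expected mutation per culture
        exp = simulate_fluctuation(mu, n_init, n_fin, 1000, np.random.default_rng(8))
        p0_obs = sum(c == 0 for c in exp.culture_counts) / 1000
        p0_theory = math.exp(-mu * (n_fin - n_init))
        se = math.sqrt(p0_theory * (1 - p0_theory) / 1000)
        assert abs(p0_obs - p0_theory) <= 3 * se

    def test_jackpot_heavy_tail(self):
        exp = simulate_fluctuation(
            2e-6, 16, 16 * 2**16, 500, np.random.default_rng(9)
        )
        counts = np.array(exp.culture_counts)
        assert counts.mean() > np.median(counts)

    def test_growth_must_be_integer_doublings(self):
        with pytest.raises(ValueError, match="2\\*\\*g"):
            simulate_fluctuation(1e-7, 10, 25, 5, np.random.default_rng(0))


class TestGenerateStudy:
    def test_byte_identical_on_rerun_and_manifest_consistency(self, tmp_path):
        """Same seed -> byte-identical files; manifest tallies equal the
        re-read, re-tallied written data (end-to-end consistency)."""
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        written = generate_study(
            a_dir, genotypes=("wild type",), n_tetrads=150, seed=5
        )
        generate_study(b_dir, genotypes=("wild type",), n_tetrads=150, seed=5)
        for pa in sorted(a_dir.iterdir()):
            assert filecmp.cmp(pa, b_dir / pa.name, shallow=False), pa.name

        from meiomap.fixtures import load_fixture

        maps = load_fixture("marker_maps")
        tet_path = written["tetrads/wild type/EAY"]
        man = json.loads(written["manifest/wild type/EAY"].read_text())
        tets = read_tetrad_table(tet_path, markers=maps["XV"].marker_names)
        tallies = tally_intervals(tets, maps["XV"])
        for (a, b), c in tallies.items():
            rec = man["tallies"]["XV"][f"{a}-{b}"]
            assert (c.PD, c.TT, c.NPD) == (rec["PD"], rec["TT"], rec["NPD"])
            assert c.parental_spores == rec["parental"]
            assert c.recombinant_spores == rec["recombinant"]

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown preset"):
            preset_config("sgs1Δ")

    def test_double_mutant_fold_decrease_in_published_range(self):
        """Downstream fold decrease (wild type / double mutant, tetrad
        cumulative per chromosome) lands in the published 5-20x range at
        n = 2000 tetrads."""
        from meiomap.stats import cumulative_distance

        folds = {}
        ests = {}
        for genotype, seed in (("wild type", 31), ("mlh3Δ mms4Δ", 32)):
            cfg = preset_config(genotype, n_tetrads=2000, seed=seed)
            tets, _ = simulate_study_genotype(cfg)
            per_chrom = {}
            for chrom, mm in cfg.maps.items():
                tallies = tally_intervals(tets, mm)
                per_chrom[chrom] = cumulative_distance(
                    [perkins_se_ci(c) for c in tallies.values()]
                ).cm
            ests[genotype] = per_chrom
        for chrom in ests["wild type"]:
            fold = ests["wild type"][chrom] / ests["mlh3Δ mms4Δ"][chrom]
            assert 5.0 <= fold <= 20.0, (chrom, fold)
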