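import numpy as np
import pytest

import haplostock as hs
from haplostock.errors import InfeasibleConfigError


class TestWildPool:
    def test_zero_divergence_all_identical(self):
        cfg = hs.SimulationConfig(seed=1, length=50, target_pi=0.0,
                                  wild_pool_size=200,
                                  background_sharing_target=1.0, n_dams=5,
                                  n_broodstock_sampled=5, n_families=3)
        pool = hs.simulate_wild_pool(cfg)
        assert len(set(pool.sequences())) == 1

    def test_pi_calibration(self):
        """Realized mean pairwise divergence of a pool sample is within 10%
        of the target."""
        cfg = hs.SimulationConfig(seed=7, length=716,
                                  polymorphic_fraction=294 / 716,
                                  target_pi=0.023, wild_pool_size=3000)
        pool = hs.simulate_wild_pool(cfg)
        rng = np.random.default_rng(7)
        take = rng.choice(pool.n, size=200, replace=False)
        sub = pool.subset([pool.ids[i] for i in take])
        pi = hs.nucleotide_diversity(hs.pairwise_distances(sub))
        assert pi == pytest.approx(0.023, rel=0.10)

    def test_pool_haplotypes_distinct(self):
        cfg = hs.SimulationConfig(seed=3, length=100, target_pi=0.02,
                                  polymorphic_fraction=0.4, wild_pool_size=2000)
        pool = hs.simulate_wild_pool(cfg)
        assert len(set(pool.sequences())) == pool.n

    def test_infeasible_target_rejected(self):
        cfg = hs.SimulationConfig(target_pi=0.8, polymorphic_fraction=0.1)
        with pytest.raises(InfeasibleConfigError):
            cfg.validate()

    def test_high_heterozygosity_uses_four_alleles(self):
        # per-column heterozygosity 0.7 > 0.5 requires >2 alleles
        cfg = hs.SimulationConfig(seed=5, length=60, target_pi=0.35,
                                  polymorphic_fraction=0.5, wild_pool_size=500)
        pool = hs.simulate_wild_pool(cfg)
        pi = hs.nucleotide_diversity(hs.pairwise_distances(
            pool.subset(pool.ids[:150])))
        assert pi == pytest.approx(0.35, rel=0.10)


class TestHatcheryCohort:
    def test_single_family_monomorphic(self):
        cfg = hs.SimulationConfig(seed=2, length=60, wild_pool_size=500,
                                  n_families=1, n_dams=5,
                                  n_broodstock_sampled=5)
        cohort, families = hs.simulate_hatchery_cohort(cfg, n=50)
        assert len(set(cohort.sequences())) == 1
        assert set(families) == {0}

    def test_equal_families(self):
        cfg = hs.SimulationConfig(seed=2, length=60, wild_pool_size=500,
                                  n_families=9, family_size_law="equal")
        cohort, families = hs.simulate_hatchery_cohort(cfg, n=900)
        counts = np.bincount(families, minlength=9)
        # multinomial with equal weights: all families used, roughly even
        assert (counts > 0).all()
        assert counts.max() < 2 * counts.min()
        assert len(set(cohort.sequences())) == 9

    def test_offspring_haplotype_equals_dam_haplotype(self):
        cfg = hs.SimulationConfig(seed=4, length=60, wild_pool_size=500,
                                  n_families=3)
        cohort, families = hs.simulate_hatchery_cohort(cfg, n=30)
        seqs = cohort.sequences()
        by_family = {}
        for s, f in zip(seqs, families):
            by_family.setdefault(f, set()).add(s)
        assert all(len(v) == 1 for v in by_family.values())

    def test_lognormal_family_sizes_match_multinomial_law(self):
        """Observed family-size histograms are consistent with multinomial
        sampling of the drawn lognormal weights (chi-square GoF)."""
        from scipy import stats as sps

        p_values = []
        for seed in range(8):
            cfg = hs.SimulationConfig(seed=seed, length=40, wild_pool_size=500,
                                      n_families=5, family_sigma=1.0)
            gen = np.random.default_rng(seed)
            from haplostock.simulate import _family_weights

            weights = _family_weights(cfg, gen)
            families = gen.choice(cfg.n_families, size=400, p=weights)
            counts = np.bincount(families, minlength=5)
            exp = 400 * weights
            keep = exp > 1e-9
            stat = ((counts[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            p_values.append(1 - sps.chi2.cdf(stat, df=keep.sum() - 1))
        assert max(p_values) > 0.01  # not systematically inconsistent


class TestEstuaryTimeseries:
    def test_full_determinism_byte_identical(self, tmp_path):
        cfg = hs.mixture_scenario(0.2, seed=9, n_stocked=60, n_reference=40)
        out1 = tmp_path / "a"
        out2 = tmp_path / "b"
        hs.simulate_estuary_timeseries(cfg).write(out1)
        hs.simulate_estuary_timeseries(cfg).write(out2)
        for name in ["alignment.fasta", "metadata.csv", "release_calendar.csv",
                     "truth.csv"]:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()

    def test_reference_sites_all_wild(self):
        cfg = hs.mixture_scenario(0.5, seed=3, n_stocked=50, n_reference=40)
        sim = hs.simulate_estuary_timeseries(cfg)
        truth = sim.truth.set_index("sample_id")
        meta = sim.data.meta.df
        ref_ids = meta.index[(meta["site_treatment"] == "reference")]
        assert (truth.loc[ref_ids, "origin"] == "wild").all()

    def test_no_stocking_no_broodstock_matches(self):
        """m = 0 everywhere: no estuary haplotype matches the broodstock."""
        cfg = hs.mixture_scenario(0.0, seed=11, n_stocked=120, n_reference=120)
        sim = hs.simulate_estuary_timeseries(cfg)
        meta = sim.data.meta.df
        brood = hs.collapse(sim.data.seqs.subset(
            list(meta.index[meta["role"] == "broodstock"])), "brood")
        for table in hs.collapse_haplotypes(
                sim.data.subset(list(meta.index[meta["role"] == "estuary"])),
                "site"):
            assert hs.match_broodstock(table, brood).n_matching_samples == 0

    def test_reference_sharing_near_background(self):
        """Reference-site sharing stays at the finite-pool background level."""
        pcts = []
        for seed in range(5):
            cfg = hs.mixture_scenario(0.0, seed=seed, n_stocked=20,
                                      n_reference=170)
            sim = hs.simulate_estuary_timeseries(cfg)
            for site in ("RefA", "RefB"):
                pcts.append(hs.temporal_sharing_profile(sim.data, site).pct_sharing)
        # expected ~ 1-2% for n=170 against a pool of 12,000
        assert 0.0 <= np.mean(pcts) < 5.0

    def test_closed_lake_early_cohorts_dominated_by_families(self):
        cfg = hs.mixture_scenario(1.0, seed=21)
        sim = hs.simulate_estuary_timeseries(cfg)
        rep = hs.temporal_sharing_profile(sim.data, "StockedLake")
        assert rep.cohorts[0].pct_sharing > 80.0
        assert rep.n_shared_groups <= cfg.n_families

    def test_default_scenario_shape(self, default_sim):
        meta = default_sim.data.meta.df
        assert default_sim.data.n == 871
        sizes = meta[meta["role"] == "estuary"].groupby("site").size()
        assert sizes.to_dict() == {"Corunna": 170, "Durras": 168,
                                   "Tabourie": 234, "Wallagoot": 253}
        assert (meta["role"] == "broodstock").sum() == 46
        assert default_sim.data.seqs.length == 716

    def test_yaml_roundtrip(self, tmp_path):
        cfg = hs.default_scenario(seed=5)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        back = hs.SimulationConfig.from_yaml(path)
        assert back == cfg


class TestEndToEndRecovery:
    def test_pipeline_recovers_design(self, default_sim):
        """End-to-end: no structure among reference sites, elevated sharing
        only at stocked sites, contribution ordered with true m."""
        sim = default_sim
        meta = sim.data.meta.df
        report = hs.run_analysis(sim.data, hs.RunConfig(seed=0, n_perm=99))
        # (a) PhiPT ~ 0 between reference sites (lower triangle holds PhiPT)
        assert report.phipt.loc["Durras", "Corunna"] < 0.05
        # (b) sharing elevated only at stocked sites
        sharing = {s: r.pct_sharing for s, r in report.sharing.items()}
        assert sharing["Wallagoot"] > sharing["Tabourie"] > max(
            sharing["Durras"], sharing["Corunna"])
        # (c) contribution ranks with true hatchery load
        contrib = {s: c.corrected_contribution_pct
                   for s, c in report.contributions.items()}
        assert contrib["Wallagoot"] > contrib["Tabourie"] >= 0.0
        # broodstock matches only at stocked sites
        for site, m in report.broodstock_matches.items():
            if site in ("Durras", "Corunna"):
                assert m.n_matching_samples == 0
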