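import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commvade.errors import ConfigurationError
from commvade.synthetic_community import (
    SimConfig,
    SimTruth,
    gas_series,
    generate_sources,
    mix,
    sample_reads,
    simulate_study,
    transfer_dynamics,
)


def small_config(**kw):
    defaults = dict(n_shared=10, n_lp_unique=5, n_hp_unique=5, n_key_taxa=2,
                    key_taxa_k=2, bottleneck_N=1000, read_depth=10_000, seed=3)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSources:
    def test_support_sizes(self, rng):
        cfg = small_config()
        lp, hp, truth = generate_sources(cfg, rng)
        assert np.count_nonzero(lp) == cfg.n_shared + cfg.n_lp_unique
        assert np.count_nonzero(hp) == cfg.n_shared + cfg.n_hp_unique
        assert lp.sum() == pytest.approx(1.0)
        assert hp.sum() == pytest.approx(1.0)

    def test_disjoint_support_without_shared(self, rng):
        cfg = small_config(n_shared=0, n_lp_unique=2, n_hp_unique=2,
                           n_key_taxa=1, key_taxa_k=1)
        lp, hp, _ = generate_sources(cfg, rng)
        assert not np.any((lp > 0) & (hp > 0))

    def test_sigma_zero_gives_equal_abundances(self, rng):
        cfg = small_config(abundance_sigma=0.0, key_taxa_rare_bias=False)
        lp, _, _ = generate_sources(cfg, rng)
        nz = lp[lp > 0]
        assert np.allclose(nz, nz[0])

    def test_key_taxa_are_hp_unique(self, rng):
        cfg = small_config()
        _, _, truth = generate_sources(cfg, rng)
        assert len(truth.key_taxa) == cfg.n_key_taxa
        assert all(truth.origin[a] == "HP_only" for a in truth.key_taxa)


class TestMix:
    def test_even_mix(self):
        assert mix(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 0.5) == pytest.approx(
            [0.5, 0.5]
        )

    def test_hand_arithmetic(self):
        out = mix(np.array([0.8, 0.2, 0.0]), np.array([0.0, 0.5, 0.5]), 0.1)
        assert out == pytest.approx([0.72, 0.23, 0.05])

    def test_small_dose_approaches_resident(self):
        lp = np.array([0.6, 0.4, 0.0])
        out = mix(lp, np.array([0.0, 0.0, 1.0]), 1e-9)
        assert out == pytest.approx(lp, abs=1e-8)

    @pytest.mark.parametrize("dose", [0.0, 1.0, -0.1, 2.0])
    def test_dose_domain(self, dose):
        with pytest.raises(ConfigurationError):
            mix(np.array([1.0]), np.array([1.0]), dose)

    @settings(max_examples=100, derandomize=True)
    @given(
        lp=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8),
        hp=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8),
        dose=st.floats(1e-6, 1.0, exclude_max=True),
    )
    def test_mix_is_convex_and_support_preserving(self, lp, hp, dose):
        n = min(len(lp), len(hp))
        lp = np.asarray(lp[:n]) + 1e-9
        hp = np.asarray(hp[:n]) + 1e-9
        lp, hp = lp / lp.sum(), hp / hp.sum()
        out = mix(lp, hp, dose)
        assert out.sum() == pytest.approx(1.0)
        assert (out >= np.minimum(lp, hp) - 1e-12).all()
        assert (out <= np.maximum(lp, hp) + 1e-12).all()


def two_taxon_truth():
    return SimTruth(
        asv_ids=["ASV0001", "ASV0002"],
        origin={"ASV0001": "shared", "ASV0002": "shared"},
    )


class TestTransferDynamics:
    def test_fixed_taxon_stays_fixed(self, rng):
        cfg = small_config()
        truth = two_taxon_truth()
        p = transfer_dynamics(np.array([1.0, 0.0]), truth, cfg, 5, rng)
        assert p == pytest.approx([1.0, 0.0])

    def test_neutral_deterministic_limit_is_identity(self, rng):
        """With s=0, no establishment threshold, and the infinite-population
        limit, any number of transfers leaves the profile unchanged."""
        cfg = small_config(invader_fitness_s=0.0, establishment_freq=0.0)
        lp, hp, truth = generate_sources(cfg, np.random.default_rng(0))
        mixed = mix(lp, hp, 0.01)
        out = transfer_dynamics(
            mixed, truth, cfg, 7, rng, selection=True, deterministic=True
        )
        assert out == pytest.approx(mixed, abs=1e-12)

    def test_single_transfer_extinction_matches_closed_form(self):
        """Neutral single-transfer loss probability is (1-f)^N."""
        f, n, reps = 1e-3, 1000, 3000
        cfg = small_config(bottleneck_N=n)
        truth = two_taxon_truth()
        profile = np.array([f, 1 - f])
        rng = np.random.default_rng(99)
        extinct = sum(
            transfer_dynamics(profile, truth, cfg, 1, rng)[0] == 0
            for _ in range(reps)
        )
        expected = (1 - f) ** n
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(extinct / reps - expected) < 3 * se

    def test_spec_rule_recovered_without_extensions(self, rng):
        """establishment_freq=0 gives plain 1+s selection on HP taxa."""
        cfg = small_config(invader_fitness_s=1.0, establishment_freq=0.0)
        truth = SimTruth(
            asv_ids=["a", "b"], origin={"a": "HP_only", "b": "LP_only"}
        )
        p = transfer_dynamics(
            np.array([0.1, 0.9]), truth, cfg, 1, rng, deterministic=True
        )
        assert p == pytest.approx([0.2 / 1.1, 0.9 / 1.1])


class TestSampleReads:
    def test_point_mass(self, rng):
        assert sample_reads(np.array([1.0, 0, 0]), 100, rng).tolist() == [100, 0, 0]

    def test_conservation(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            assert sample_reads(p, 4321, rng).sum() == 4321

    def test_binomial_se(self, rng):
        counts = sample_reads(np.array([0.5, 0.5]), 10**6, rng)
        assert abs(counts[0] - 5e5) < 3 * np.sqrt(10**6 * 0.25)


class TestGasSeries:
    def gas_config(self, **kw):
        defaults = dict(
            gas_base_rate=10.0, gas_boost_rate=30.0, gas_hp_rate=25.0,
            gas_lag_weeks=4, gas_noise_sd=0.0, n_key_taxa=1, key_taxa_k=1,
        )
        defaults.update(kw)
        return small_config(**defaults)

    def truth_with_key(self):
        t = SimTruth(asv_ids=["k", "x"], origin={"k": "HP_only", "x": "shared"})
        t.key_taxa = ["k"]
        return t

    def test_key_taxa_absent_means_base_rate(self):
        cfg = self.gas_config()
        rows = gas_series(np.array([0.0, 1.0]), self.truth_with_key(), cfg, 2)
        assert rows[-1]["cumulative_gas_ml"] == pytest.approx(10.0 * cfg.n_weeks)

    def test_boost_after_lag_hand_arithmetic(self):
        """base=10, boost=30, lag=4, invasion week 2, 8 weeks: 6*10+2*30."""
        cfg = self.gas_config()
        assert cfg.n_weeks == 8
        rows = gas_series(np.array([0.5, 0.5]), self.truth_with_key(), cfg, 2)
        assert rows[-1]["cumulative_gas_ml"] == pytest.approx(120.0)

    def test_no_lag_full_boost(self):
        cfg = self.gas_config(gas_lag_weeks=0)
        rows = gas_series(np.array([0.5, 0.5]), self.truth_with_key(), cfg, 0)
        assert rows[-1]["cumulative_gas_ml"] == pytest.approx(30.0 * cfg.n_weeks)

    def test_pure_hp_always_boosted(self):
        cfg = self.gas_config()
        rows = gas_series(
            np.array([0.0, 1.0]), self.truth_with_key(), cfg, 2, treatment="HP"
        )
        assert rows[-1]["cumulative_gas_ml"] == pytest.approx(25.0 * cfg.n_weeks)

    def test_cumulative_is_monotone_with_noise(self, rng):
        cfg = self.gas_config(gas_noise_sd=50.0)
        rows = gas_series(
            np.array([0.5, 0.5]), self.truth_with_key(), cfg, 2, rng=rng
        )
        vals = [r["cumulative_gas_ml"] for r in rows]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestSimulateStudy:
    def test_sample_count_with_and_without_drop(self):
        cfg = small_config()
        assert simulate_study(cfg).table.shape[0] == 29
        cfg2 = small_config(drop_hp_sample=False)
        assert simulate_study(cfg2).table.shape[0] == 30

    def test_same_seed_is_byte_identical(self):
        a = simulate_study(small_config())
        b = simulate_study(small_config())
        assert np.array_equal(a.table.counts, b.table.counts)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.gas.frame.equals(b.gas.frame)
        assert a.truth.origin == b.truth.origin

    def test_substreams_stable_under_fewer_replicates(self):
        """Per-sample streams are keyed by (treatment, replicate), so
        removing replicates never perturbs the remaining samples."""
        full = simulate_study(small_config())
        fewer = simulate_study(small_config(replicates=4))
        assert np.array_equal(fewer.table.sample("LP_R1"), full.table.sample("LP_R1"))
        assert np.array_equal(
            fewer.table.sample("D10_R2"), full.table.sample("D10_R2")
        )

    def test_metadata_and_gas_cover_dropped_sample(self):
        study = simulate_study(small_config())
        dropped = f"HP_R{study.config.replicates}"
        assert dropped not in study.table.sample_ids
        assert dropped in study.metadata.sample_ids
        assert dropped in study.gas.sample_ids

    def test_tree_covers_all_asvs(self):
        study = simulate_study(small_config())
        assert sorted(study.tree.leaf_names) == sorted(study.table.asv_ids)
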