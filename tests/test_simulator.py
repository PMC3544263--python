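"""Forward Wright-Fisher simulator: map function, founding, selection,
drift moments, and the split experiment."""

import numpy as np
import pandas as pd
import pytest

from hitchmap.simulator import (
    SimConfig,
    derive_ne,
    evolve,
    fitness_vector,
    found_ancestral,
    founder_sample_linked,
    haldane_r,
    population_from_freqs,
    rec_fractions,
    replicate_boxplot_stats,
    run_split_experiment,
)


class TestParameterisation:
    def test_fitness_vector_heterozygote(self):
        assert fitness_vector(0.6, 0.5) == (1.0, 0.7, 0.4)

    def test_fitness_out_of_range(self):
        with pytest.raises(ValueError):
            fitness_vector(1.5, 0.5)

    @pytest.mark.parametrize("t,fst,ne", [(8, 0.01212, 330), (5, 0.0385, 65), (5, 0.0105, 238)])
    def test_derive_ne_inverts_printed_values(self, t, fst, ne):
        assert derive_ne(t, fst) == ne

    def test_derive_ne_zero_fst_raises(self):
        with pytest.raises(ValueError):
            derive_ne(5, 0.0)


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_r(0.0) == 0.0

    def test_eight_cm(self):
        assert haldane_r(8.0) == pytest.approx(0.073928, abs=1e-6)

    def test_free_recombination_limit(self):
        assert haldane_r(1e6) == pytest.approx(0.5)
        grid = np.linspace(0, 200, 50)
        r = haldane_r(grid)
        assert (np.diff(r) > 0).all() and (r < 0.5).all()

    def test_rec_fractions_lg_boundary_is_half(self):
        r = rec_fractions(np.array([0.0, 10.0, 0.0]), np.array(["a", "a", "b"]))
        assert r[1] == 0.5 and r[0] < 0.5


class TestFounding:
    def test_systematic_expansion_preserves_counts(self, rng):
        src = rng.integers(1, 3, (8, 3, 2)).astype(np.int32)
        pop = found_ancestral(src, 32, burnin=0, r=np.full(2, 0.5), rng=rng, systematic=True)
        for j in range(3):
            a_src = np.bincount(src[:, j, :].ravel(), minlength=3)
            a_pop = np.bincount(pop[:, j, :].ravel(), minlength=3)
            np.testing.assert_array_equal(a_pop, 4 * a_src)

    def test_burnin_preserves_frequencies_at_large_ne(self, rng):
        freqs = [np.array([0.7, 0.3]), np.array([0.5, 0.5])]
        src = population_from_freqs(freqs, 200, rng)
        pop = found_ancestral(src, 10_000, burnin=3, r=np.full(1, 0.5), rng=rng)
        for j, f in enumerate(freqs):
            p_src = (src[:, j, :] == 2).mean()
            p_pop = (pop[:, j, :] == 2).mean()
            # founding + 3 generations of drift at N = 10^4
            se = np.sqrt(4 * p_src * (1 - p_src) / (2 * 10_000))
            assert abs(p_pop - p_src) <= 4 * se

    def test_missing_calls_imputed(self, rng):
        src = np.full((6, 1, 2), 1, dtype=np.int32)
        src[0] = 0
        pop = found_ancestral(src, 12, burnin=0, r=np.empty(0), rng=rng)
        assert (pop > 0).all()

    def test_seeded_determinism(self):
        src = np.random.default_rng(0).integers(1, 3, (8, 3, 2)).astype(np.int32)
        a = found_ancestral(src, 30, 2, np.full(2, 0.5), np.random.default_rng(4))
        b = found_ancestral(src, 30, 2, np.full(2, 0.5), np.random.default_rng(4))
        np.testing.assert_array_equal(a, b)


class TestEvolve:
    def test_neutral_drift_moments(self):
        """One neutral generation: mean change ~0, variance ~p(1-p)/(2N)."""
        rng = np.random.default_rng(12)
        N, L = 200, 600
        pop = population_from_freqs([np.array([0.5, 0.5])] * L, N, rng)
        p0 = (pop == 2).mean(axis=(0, 2))
        new, _ = evolve(pop, 1, np.full(L - 1, 0.5), rng)
        p1 = (new == 2).mean(axis=(0, 2))
        d = p1 - p0
        assert abs(d.mean()) < 3 * np.sqrt(0.25 / (2 * N) / L)
        var_expected = np.mean(p0 * (1 - p0)) / (2 * N)
        assert d.var() == pytest.approx(var_expected, rel=0.25)

    def test_selection_matches_deterministic_recursion(self):
        """s=0.6, h=0.5, p0=0.1 at N=10^4: one generation gives p ~ 0.1587."""
        gains = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pop = population_from_freqs([np.array([0.9, 0.1])], 10_000, rng)
            p0 = (pop == 2).mean()
            _, traj = evolve(pop, 1, np.empty(0), rng, selected_idx=0,
                             favored=2, s=0.6, h=0.5)
            # compare against the recursion evaluated at the realised p0
            q0 = 1 - p0
            wbar = p0**2 + 2 * p0 * q0 * 0.7 + q0**2 * 0.4
            p_exp = (p0**2 + p0 * q0 * 0.7) / wbar
            gains.append(traj[1] - p_exp)
        assert abs(np.mean(gains)) <= 3 * np.sqrt(0.16 / (2 * 10_000) / 10)

    def test_unlinked_loci_uncorrelated(self):
        rng = np.random.default_rng(5)
        pop = population_from_freqs([np.array([0.5, 0.5])] * 2, 2000, rng)
        new, _ = evolve(pop, 3, np.array([0.5]), rng)
        g = (new == 2).sum(axis=2)  # genotype dosage per locus
        corr = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        assert abs(corr) < 0.1

    def test_all_zero_fitness_raises(self):
        rng = np.random.default_rng(0)
        pop = np.full((10, 1, 2), 2, dtype=np.int32)  # all aa, w = 1 - s = 0
        with pytest.raises(ValueError, match="fitness"):
            evolve(pop, 1, np.empty(0), rng, selected_idx=0, favored=1, s=1.0, h=0.5)


class TestSplitExperiment:
    def _drift_cfg(self, L=60, **kw):
        defaults = dict(
            ne=65, t_split=5,
            loci=[f"L{j}" for j in range(L)],
            positions_cM=np.zeros(L), linkage_groups=np.arange(L),
            burnin=0, sample_size=16, n_replicates=50, seed=1,
        )
        defaults.update(kw)
        return SimConfig(**defaults)

    def test_trajectory_length_is_t_plus_one(self, rng):
        cfg = self._drift_cfg(L=5, n_replicates=2, selected_locus="L0")
        freqs = [np.array([0.7, 0.3])] * 5
        reps = run_split_experiment(cfg, ancestral_freqs=freqs)
        assert len(reps[0].traj_captive) == cfg.t_split + 1
        assert np.isfinite(reps[0].traj_captive).all()

    def test_selected_minor_allele_rises_in_captive_only(self):
        cfg = self._drift_cfg(L=3, ne=500, n_replicates=10, selected_locus="L0", seed=3)
        freqs = [np.array([0.8, 0.2])] * 3
        reps = run_split_experiment(cfg, ancestral_freqs=freqs)
        gain_c = np.mean([r.traj_captive[-1] - r.traj_captive[0] for r in reps])
        gain_w = np.mean([r.traj_wild[-1] - r.traj_wild[0] for r in reps])
        assert gain_c > 0.2
        assert abs(gain_w) < 0.1

    def test_monomorphic_selected_locus_raises(self):
        cfg = self._drift_cfg(L=2, n_replicates=1, selected_locus="L0")
        freqs = [np.array([1.0, 0.0]), np.array([0.5, 0.5])]
        with pytest.raises(ValueError, match="monomorphic"):
            run_split_experiment(cfg, ancestral_freqs=freqs)

    def test_full_determinism_under_seed(self):
        cfg = self._drift_cfg(L=10, n_replicates=3)
        freqs = [np.array([0.6, 0.4])] * 10
        r1 = run_split_experiment(cfg, ancestral_freqs=freqs)
        r2 = run_split_experiment(cfg, ancestral_freqs=freqs)
        for a, b in zip(r1, r2):
            pd.testing.assert_series_equal(a.per_locus_theta, b.per_locus_theta)

    def test_linkage_decay_monotone_in_map_distance(self):
        """Hitchhiking excess theta decreases with distance from the
        selected locus (complete founder association at every flank)."""
        loci = ["sel", "d0", "d1", "d8", "d33"]
        pos = np.array([10.0, 10.0, 11.0, 18.0, 43.6])
        mafs = np.full(5, 0.25)
        means = {}
        for mode in ("sel", "drift"):
            acc = np.zeros(5)
            for k in range(100):
                src = founder_sample_linked(
                    mafs, 16, 0, np.array([0.0, 1, 1, 1, 1]),
                    np.random.default_rng(7000 + k),
                )
                cfg = SimConfig(
                    ne=238, t_split=5, loci=loci, positions_cM=pos,
                    selected_locus="sel" if mode == "sel" else None,
                    s=0.6, h=0.5, burnin=3, sample_size=16,
                    n_replicates=1, seed=k,
                )
                rep = run_split_experiment(cfg, source_calls=src)[0]
                acc += np.nan_to_num(rep.per_locus_theta.to_numpy()) / 100
            means[mode] = acc
        excess = means["sel"] - means["drift"]
        flank_excess = excess[1:]  # d0, d1, d8, d33
        assert (np.diff(flank_excess) <= 0.02).all()  # non-increasing (MC slack)
        assert flank_excess[0] > 0.15 and flank_excess[-1] < 0.1


class TestBoxplotStats:
    def test_constant_values_zero_width(self):
        st = replicate_boxplot_stats(np.full(25, 0.3))
        assert st["q1"] == st["q3"] == st["median"] == 0.3
        assert len(st["outliers"]) == 0

    def test_matches_direct_quantiles(self, rng):
        v = rng.normal(size=25)
        st = replicate_boxplot_stats(v)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        assert st["median"] == pytest.approx(med)
        assert st["q1"] == pytest.approx(q1) and st["q3"] == pytest.approx(q3)

    def test_outlier_definition(self):
        v = np.concatenate([np.arange(1.0, 22.0), [100.0]])
        st = replicate_boxplot_stats(v)
        iqr = st["q3"] - st["q1"]
        assert list(st["outliers"]) == [100.0]
        assert st["whisker_high"] <= st["q3"] + 1.5 * iqr
        assert 100.0 > st["q3"] + 1.5 * iqr

    def test_too_few_values_raises(self):
        with pytest.raises(ValueError):
            replicate_boxplot_stats(np.array([1.0, 2.0]))
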