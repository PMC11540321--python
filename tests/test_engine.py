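import numpy as np
import pytest

import msdiv
from msdiv import engine


class TestFitness:
    def test_optimum_gives_one(self):
        assert msdiv.fitness(1.0, 1.0, 5.0) == 1.0

    def test_printed_formula(self):
        # z - theta = 2, V_S = 5 -> exp(-0.4)
        assert msdiv.fitness(1.0, -1.0, 5.0) == pytest.approx(np.exp(-0.4))

    def test_neutral_control_regime(self):
        # V_S = 1e9 makes any bounded phenotype effectively neutral
        assert msdiv.fitness(10.0, -10.0, 1e9) == pytest.approx(1.0, abs=1e-6)

    def test_patch_scaling_preserves_ranking(self):
        w = msdiv.fitness(np.array([0.0, 0.5, 1.0]), 1.0, 5.0)
        scaled = msdiv.patch_scaled_fitness(w)
        assert np.allclose(scaled / scaled.sum(), w / w.sum())
        assert scaled.mean() == pytest.approx(1.0)


class TestPhenotype:
    def test_additive_nonredundant_optimum(self):
        # l = 4 loci, homozygous for +1/(2l) everywhere -> z = 1
        gm = msdiv.unlinked_loci_map(4)
        g = np.full((1, 1, 2, 4), 1.0 / 8)
        assert msdiv.phenotype(g, gm)[0, 0] == pytest.approx(1.0)

    def test_redundant_two_locus_optimum(self):
        # +0.25 homozygous at exactly 2 of 20 loci, the rest cancelling -> z = 1
        gm = msdiv.unlinked_loci_map(20)
        g = np.zeros((1, 1, 2, 20))
        g[0, 0, :, :2] = 0.25
        assert msdiv.phenotype(g, gm)[0, 0] == pytest.approx(1.0)

    def test_neutral_loci_do_not_contribute(self, tiny_map):
        g = np.ones((1, 2, 2, 3))
        g[:, :, :, tiny_map.selected_idx] = 0.0
        assert np.all(msdiv.phenotype(g, tiny_map) == 0.0)


class TestMigrationMatrix:
    def test_two_patch_exchange(self):
        p = msdiv.SimulationParams(N=10, m=0.1)
        M = msdiv.migration_matrix(p)
        assert np.allclose(M, [[0.9, 0.1], [0.1, 0.9]])

    def test_stepping_stone_rows(self):
        p = msdiv.SimulationParams(N=10, m=0.1, d=10)
        M = msdiv.migration_matrix(p)
        assert np.allclose(M.sum(axis=1), 1.0)
        assert M[5, 4] == M[5, 6] == pytest.approx(0.05)
        assert M[5, 5] == pytest.approx(0.90)
        assert M[0, 1] == pytest.approx(0.05)
        assert M[0, 0] == pytest.approx(0.95)
        # no migration beyond adjacent patches
        assert np.count_nonzero(M[5]) == 3
        assert np.count_nonzero(M[0]) == 2

    def test_interior_terminal_influx_ratio_is_two(self):
        p = msdiv.SimulationParams(N=10, m=0.2, d=10)
        M = msdiv.migration_matrix(p)
        interior = 1.0 - M[5, 5]
        terminal = 1.0 - M[0, 0]
        assert interior / terminal == pytest.approx(2.0)


class TestInitialize:
    def test_shapes_and_initial_frequencies(self, default_map, rng):
        p = msdiv.SimulationParams(N=1000, m=0.1)
        st = msdiv.initialize(p, default_map, rng)
        assert st.shape == (2, 1000, 2, 75)
        neu = st.genotypes[:, :, :, default_map.neutral_idx]
        assert set(np.unique(neu)) == {0.0, 1.0}
        assert neu.mean() == pytest.approx(0.5, abs=0.01)
        # continuum selected loci start monomorphic at 0
        assert np.all(st.genotypes[:, :, :, default_map.selected_idx] == 0.0)

    def test_diallelic_adaptive_initialized_polymorphic(self, rng):
        gm = msdiv.unlinked_loci_map(10)
        p = msdiv.SimulationParams(
            N=500, m=0.0, effect_model=msdiv.REDUNDANT, n_adaptive=10
        )
        st = msdiv.initialize(p, gm, rng)
        vals = np.unique(st.genotypes)
        assert set(vals) == {-0.25, 0.25}
        assert (st.genotypes > 0).mean() == pytest.approx(0.5, abs=0.02)

    def test_seed_determinism(self, default_map):
        p = msdiv.SimulationParams(N=50, m=0.1, seed=7)
        a = msdiv.initialize(p, default_map)
        b = msdiv.initialize(p, default_map)
        assert np.array_equal(a.genotypes, b.genotypes)


class TestRecombine:
    def test_no_recombination_returns_parental_haplotype(self, rng):
        gm = msdiv.unlinked_loci_map(1, 0)
        parent = np.array([[1.0, 1, 1, 1], [0.0, 0, 0, 0]])[:, :, None][:, 0, :]
        # build a 4-locus fully linked map
        from msdiv.genmap import GeneticMap, LocusSpec

        loci = [LocusSpec(i, "neutral", 0, float(i)) for i in range(4)]
        gm = GeneticMap(loci, np.zeros(3), 1)
        parent = np.stack([np.ones(4), np.zeros(4)])
        for _ in range(20):
            gam = msdiv.recombine(parent, gm, rng)
            assert np.all(gam == gam[0])

    def test_switch_frequency_binomial_oracle(self, rng):
        """A single r = 0.1 interval: switch frequency within 3 SE of 0.1."""
        from msdiv.genmap import GeneticMap, LocusSpec

        loci = [LocusSpec(0, "neutral", 0, -5.0), LocusSpec(1, "neutral", 0, 5.0)]
        gm = GeneticMap(loci, np.array([0.1]), 1)
        n = 100_000
        parents = np.broadcast_to(
            np.array([[1.0, 1.0], [0.0, 0.0]]), (n, 2, 2)
        ).copy()
        gams = engine._recombine_batch(parents, gm.rec_fractions, rng)
        switch_rate = (gams[:, 0] != gams[:, 1]).mean()
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(switch_rate - 0.1) < 3 * se

    def test_sparse_switch_events_rate(self, rng):
        """The sparse crossover sampler reproduces per-interval Bernoulli
        rates for both its sparse and dense code paths."""
        rec = np.array([1e-3, 0.02, 0.5])  # sparse, sparse, dense
        n = 40_000
        counts = np.zeros(3)
        ev_g, ev_i = engine._switch_events(n, rec, rng)
        for i in range(3):
            counts[i] = (ev_i == i).sum()
        for i, r in enumerate(rec):
            se = np.sqrt(n * r * (1 - r))
            assert abs(counts[i] - n * r) < 4 * se


class TestMutate:
    def _state(self, gm, p, rng):
        return msdiv.initialize(p, gm, rng)

    def test_zero_rate_is_identity(self, default_map, rng):
        p = msdiv.SimulationParams(N=50, m=0.1, mu_neutral=0.0, mu_adaptive=0.0)
        st = self._state(default_map, p, rng)
        before = st.genotypes.copy()
        msdiv.mutate(st, p, default_map, rng)
        assert np.array_equal(st.genotypes, before)

    def test_neutral_flip_count_poisson_oracle(self, rng):
        """1e6 neutral allele-generations at mu = 1e-5: ~10 flips."""
        gm = msdiv.unlinked_loci_map(1, 100)
        p = msdiv.SimulationParams(N=50, m=0.0, mu_neutral=1e-5, mu_adaptive=0.0)
        st = self._state(gm, p, rng)
        flips = 0
        reps = 50  # 50 x (2*50*2*100) = 1e6 allele-generations
        base = st.genotypes.copy()
        for _ in range(reps):
            st.genotypes[:] = base
            msdiv.mutate(st, p, gm, rng)
            flips += int(
                (st.genotypes[:, :, :, gm.neutral_idx]
                 != base[:, :, :, gm.neutral_idx]).sum()
            )
        # Poisson(10): 4 sigma band
        assert 10 - 4 * np.sqrt(10) < flips < 10 + 4 * np.sqrt(10)

    def test_house_of_cards_flips_sign(self, rng):
        gm = msdiv.unlinked_loci_map(20)
        p = msdiv.SimulationParams(
            N=100, m=0.0, effect_model=msdiv.REDUNDANT, n_adaptive=20,
            mu_neutral=0.0, mu_adaptive=0.05,
        )
        st = self._state(gm, p, rng)
        before = st.genotypes.copy()
        msdiv.mutate(st, p, gm, rng)
        changed = st.genotypes != before
        assert changed.any()
        assert np.all(st.genotypes[changed] == -before[changed])
        assert set(np.unique(st.genotypes)) == {-0.25, 0.25}

    def test_continuum_increment_is_gaussian_shift(self, rng):
        gm = msdiv.unlinked_loci_map(1)
        p = msdiv.SimulationParams(N=500, m=0.0, mu_neutral=0.0, mu_adaptive=0.5)
        st = self._state(gm, p, rng)
        msdiv.mutate(st, p, gm, rng)
        delta = st.genotypes.ravel()
        moved = delta[delta != 0]
        assert len(moved) > 400
        assert abs(moved.mean()) < 0.2
        assert 0.8 < moved.std() < 1.2


class TestStepGeneration:
    def test_census_and_domain_closure(self, default_map, rng):
        p = msdiv.SimulationParams(N=40, m=0.1, V_S=5.0, mu_adaptive=1e-3)
        st = msdiv.initialize(p, default_map, rng)
        for _ in range(20):
            st = msdiv.step_generation(st, p, default_map, rng)
        assert st.shape == (2, 40, 2, 75)
        assert st.generation == 20
        neu = st.genotypes[:, :, :, default_map.neutral_idx]
        assert set(np.unique(neu)) <= {0.0, 1.0}

    def test_diallelic_domain_closure(self, rng):
        gm = msdiv.unlinked_loci_map(10)
        p = msdiv.SimulationParams(
            N=40, m=0.05, effect_model=msdiv.NONREDUNDANT, n_adaptive=10,
            mu_adaptive=1e-3,
        )
        st = msdiv.initialize(p, gm, rng)
        a = p.adaptive_allele_effect
        assert a == pytest.approx(1.0 / 20)
        for _ in range(20):
            st = msdiv.step_generation(st, p, gm, rng)
        assert set(np.round(np.unique(st.genotypes), 12)) <= {-a, a}

    def test_run_determinism_by_seed(self, tiny_map):
        p = msdiv.SimulationParams(
            N=20, m=0.1, generations=60, sample_every=20, seed=11
        )
        r1 = msdiv.run(p, tiny_map)
        r2 = msdiv.run(p, tiny_map)
        assert r1.metrics.equals(r2.metrics)
        assert np.array_equal(
            r1.final_state.genotypes, r2.final_state.genotypes
        )

    def test_neutral_drift_heterozygosity_decay(self):
        """m=0, neutral: mean H decays as (1 - 1/2N)^t (classical drift)."""
        gm = msdiv.unlinked_loci_map(1, 60)
        N, t = 20, 40
        hets = []
        for seed in range(15):
            p = msdiv.SimulationParams(
                N=N, m=0.0, V_S=1e9, mu_neutral=0.0, mu_adaptive=0.0,
                generations=t, sample_every=t, seed=seed,
            )
            res = msdiv.run(p, gm)
            fin = res.metrics[res.metrics.generation == t]
            # biased H (undo the n/(n-1) census correction) for the comparison
            hets.append(fin[fin.kind == "neutral"].pi_w_mean.mean()
                        * (2 * N - 1) / (2 * N))
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        got = np.mean(hets)
        assert got == pytest.approx(expected, rel=0.15)

    def test_high_migration_behaves_panmictic(self):
        """m=0.5, d=2, neutral: the two patches are one population of 2N,
        so F_ST stays near zero."""
        gm = msdiv.unlinked_loci_map(1, 40)
        p = msdiv.SimulationParams(
            N=50, m=0.5, V_S=1e9, mu_neutral=1e-3, mu_adaptive=0.0,
            generations=500, sample_every=500, seed=5,
        )
        res = msdiv.run(p, gm)
        fin = res.metrics[res.metrics.generation == 500]
        assert abs(fin.fst.dropna().mean()) < 0.05

    def test_patch_exchangeability_symmetric_optima(self):
        """With theta = (-1, +1) the joint law of patch-mean phenotypes is
        mirror-symmetric, so E[zbar_0 + zbar_1] = 0."""
        gm = msdiv.unlinked_loci_map(1)
        sums = []
        for seed in range(12):
            p = msdiv.SimulationParams(
                N=30, m=0.01, V_S=5.0, mu_adaptive=1e-2 / 30,
                generations=600, sample_every=600, seed=seed,
            )
            res = msdiv.run(p, gm)
            fin = res.phenotypes[res.phenotypes.generation == 600]
            sums.append(fin.mean_z.sum())
        assert abs(np.mean(sums)) < 3 * np.std(sums) / np.sqrt(len(sums)) + 0.25

    def test_ten_patch_smoke(self, rng):
        """Stepping-stone run: census conservation and a monotone-ish
        phenotypic cline across the linear optimum gradient."""
        gm = msdiv.unlinked_loci_map(1, 5)
        p = msdiv.SimulationParams(
            N=30, m=0.05, V_S=5.0, d=10, mu_adaptive=1e-2 / 30,
            generations=1500, sample_every=1500, seed=4,
        )
        res = msdiv.run(p, gm)
        assert res.final_state.shape == (10, 30, 2, 6)
        fin = res.phenotypes[res.phenotypes.generation == 1500]
        z = fin.sort_values("patch").mean_z.to_numpy()
        # ends of the cline track the ends of the optimum gradient
        assert z[-1] - z[0] > 0.5

    def test_haplotype_dump_roundtrip(self, tiny_map, tmp_path, rng):
        p = msdiv.SimulationParams(N=5, m=0.1, seed=3)
        st = msdiv.initialize(p, tiny_map, rng)
        path = tmp_path / "haps.tsv.gz"
        msdiv.dump_haplotypes(st, tiny_map, path)
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        assert len(df) == 2 * 5 * 2
        back = df[["0", "1", "2"]].to_numpy().reshape(2, 5, 2, 3)
        assert np.array_equal(back, st.genotypes)

    def test_divergence_under_selection(self):
        """Divergent optima at modest migration: patch phenotypes separate."""
        gm = msdiv.unlinked_loci_map(1)
        p = msdiv.SimulationParams(
            N=100, m=1e-3, V_S=5.0, mu_adaptive=1e-4,
            generations=3000, sample_every=3000, seed=2,
        )
        res = msdiv.run(p, gm)
        fin = res.phenotypes[res.phenotypes.generation == 3000]
        z = fin.set_index("patch").mean_z
        assert z[1] - z[0] > 1.0
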