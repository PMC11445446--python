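import numpy as np
import pytest
from scipy import stats

from crevo.equilibrium import compute_equilibrium
from crevo.mutation import (
    MutationError,
    dfe_correlation,
    enumerate_dfe,
    invasion_fitness,
    knockin,
    knockout,
    monoculture_fitness,
    multi_mutation,
)
from crevo.sampling import Environment, Strain, make_environment, sample_pool


class TestMutationConstruction:
    def test_knockout_renormalizes_and_records_norm(self):
        p = Strain("p", 0.0, np.array([0.5, 0.5]))
        m = knockout(p, 1)
        np.testing.assert_allclose(p.alpha + m.d_alpha, [1.0, 0.0])
        np.testing.assert_allclose(m.norm_d_alpha, np.sqrt(0.5))

    def test_uniform_parent_knockout_norm_is_inverse_sqrt_k_km1(self):
        # uniform parent on k resources: ||d_alpha|| = 1/sqrt(k(k-1))
        for k in (2, 5, 40):
            alpha = np.zeros(50)
            alpha[:k] = 1.0 / k
            m = knockout(Strain("p", 0.0, alpha), 0)
            np.testing.assert_allclose(
                m.norm_d_alpha, 1.0 / np.sqrt(k * (k - 1)), rtol=1e-12)

    def test_knockin_uniform_enlargement(self):
        p = Strain("p", 0.0, np.array([0.5, 0.5, 0.0]))
        m = knockin(p, 2)
        np.testing.assert_allclose(p.alpha + m.d_alpha, [1 / 3] * 3)
        np.testing.assert_allclose(m.norm_d_alpha, np.sqrt(1 / 6), rtol=1e-12)

    def test_knockout_errors(self):
        p = Strain("p", 0.0, np.array([1.0, 0.0]))
        with pytest.raises(MutationError):
            knockout(p, 1)          # unused target
        with pytest.raises(MutationError):
            knockout(p, 0)          # last used resource

    def test_knockin_requires_unused_target(self):
        p = Strain("p", 0.0, np.array([0.5, 0.5]))
        with pytest.raises(MutationError):
            knockin(p, 0)

    def test_multi_mutation_validation(self):
        p = Strain("p", 0.0, np.array([0.5, 0.5]))
        budget = multi_mutation(p, np.zeros(2), dX=0.01)
        assert budget.kind == "budget_only"
        with pytest.raises(MutationError):
            multi_mutation(p, np.array([0.5, 0.5]))       # nonzero sum
        with pytest.raises(MutationError):
            multi_mutation(p, np.array([0.6, -0.6]))      # negative entry


class TestInvasionFitness:
    def test_unchanged_survivor_reintroduction_is_neutral(self,
                                                          medium_community):
        _, _, st = medium_community
        p = st.survivor_strains()[0]
        m = multi_mutation(p, np.zeros(st.env.R), dX=0.0)
        s_exact, s_approx = invasion_fitness(st, m)
        assert abs(s_exact) < 1e-10 and abs(s_approx) < 1e-12

    def test_budget_only_is_exactly_expm1(self, medium_community):
        _, _, st = medium_community
        p = st.survivor_strains()[0]
        s_exact, s_approx = invasion_fitness(
            st, multi_mutation(p, np.zeros(st.env.R), dX=0.02))
        np.testing.assert_allclose(s_exact, np.expm1(0.02), rtol=1e-10)
        np.testing.assert_allclose(s_approx, 0.02)

    def test_skewed_monoculture_knockout_hand_value(self, skewed_monoculture):
        # kappa=(3/4,1/4), r=(1/2,1/2): g=(1/2,-1/2); dropping the scarce
        # resource gives s = 0.5 both exactly and in the linearized form
        parent, env, state = skewed_monoculture
        m = knockout(parent, 1)
        s_exact, s_approx = invasion_fitness(state, m)
        np.testing.assert_allclose(s_exact, 0.5, atol=1e-10)
        np.testing.assert_allclose(s_approx, 0.5, atol=1e-10)
        np.testing.assert_allclose(monoculture_fitness(parent, env, m), 0.5,
                                   atol=1e-10)

    def test_nonsurvivor_parent_rejected(self, medium_community):
        _, _, st = medium_community
        excluded_idx = int(np.flatnonzero(~st.survivor_mask)[0])
        p = st.strains[excluded_idx]
        with pytest.raises(MutationError):
            invasion_fitness(st, knockout(p, int(p.support[0])))

    def test_exact_matches_linearized_at_dense_usage(self):
        # R0/R >= 0.2 and uniform supply: the linearized community form
        # tracks the exact rare-invader growth rate closely
        env = make_environment(50)
        pool = sample_pool(50, 15, 300, std_X=0.05, seed=9)
        st = compute_equilibrium(pool, env)
        df = enumerate_dfe(st).samples
        gaps = np.abs(df["s_inv"] - df["s_inv_approx"])
        rel = gaps / np.maximum(np.abs(df["s_inv"]), 1e-6)
        assert np.median(rel) < 0.05


class TestEnumerateDFE:
    def test_matches_direct_evaluation(self, medium_community_cv):
        _, env, st = medium_community_cv
        dfe = enumerate_dfe(st, kinds=("knockout", "knockin"), dX=0.003,
                            include_monoculture=True)
        rng = np.random.default_rng(0)
        sub = dfe.samples.sample(30, random_state=2)
        for row in sub.itertuples():
            parent = st.strains[st.index_of(row.parent_id)]
            maker = knockout if row.kind == "knockout" else knockin
            mut = maker(parent, int(row.target), row.dX)
            s_exact, s_approx = invasion_fitness(st, mut)
            np.testing.assert_allclose(s_exact, row.s_inv, atol=1e-12)
            np.testing.assert_allclose(s_approx, row.s_inv_approx, atol=1e-12)
            np.testing.assert_allclose(mut.norm_d_alpha, row.norm_d_alpha,
                                       rtol=1e-10)
            if row.kind == "knockout":
                np.testing.assert_allclose(
                    monoculture_fitness(parent, env, mut), row.s_mono,
                    atol=1e-10)

    def test_knockout_count_is_total_support(self, medium_community):
        _, _, st = medium_community
        dfe = enumerate_dfe(st, kinds=("knockout",))
        expected = sum(len(s.support) for s in st.survivor_strains()
                       if len(s.support) >= 2)
        assert len(dfe) == expected

    def test_constant_dX_shifts_whole_dfe(self, medium_community):
        _, _, st = medium_community
        base = enumerate_dfe(st, dX=0.0).samples["s_inv_approx"].to_numpy()
        shifted = enumerate_dfe(st, dX=-0.01).samples["s_inv_approx"].to_numpy()
        np.testing.assert_allclose(shifted, base - 0.01, atol=1e-12)

    def test_kinds_statistically_indistinguishable_at_matched_norm(self):
        # knockout, knockin, and norm-matched multi-resource mutations draw
        # from one underlying Gaussian once scaled by ||d_alpha||
        env = make_environment(100)
        pool = sample_pool(100, 25, 600, std_X=0.03, seed=77)
        st = compute_equilibrium(pool, env)
        df = enumerate_dfe(st, kinds=("knockout", "knockin")).samples
        scaled = df["s_inv"] / df["norm_d_alpha"]
        ko = scaled[df["kind"] == "knockout"]
        ki = scaled[df["kind"] == "knockin"]
        assert len(ko) > 1000 and len(ki) > 1000
        assert stats.ks_2samp(ko, ki).pvalue > 0.01
        # random norm-matched multi mutations on one parent
        parent = max(st.survivor_strains(), key=lambda s: len(s.support))
        supp = parent.support
        target_norm = 1.0 / len(supp)
        rng = np.random.default_rng(5)
        multi_s = []
        for _ in range(400):
            d = rng.normal(size=len(supp))
            d -= d.mean()
            d *= target_norm / np.linalg.norm(d)
            if np.any(parent.alpha[supp] + d < 0):
                continue
            da = np.zeros(env.R)
            da[supp] = d
            s_exact, _ = invasion_fitness(st, multi_mutation(parent, da))
            multi_s.append(s_exact / target_norm)
        assert stats.ks_2samp(np.asarray(multi_s), ko).pvalue > 0.01

    def test_dfe_width_similar_across_parents(self):
        # per-strain DFEs share a common scale (no strain-identity effect)
        env = make_environment(100)
        pool = sample_pool(100, 25, 600, std_X=0.03, seed=78)
        st = compute_equilibrium(pool, env)
        df = enumerate_dfe(st).samples
        groups = [g["s_inv"].to_numpy() for _, g in df.groupby("parent_id")
                  if len(g) >= 10]
        assert stats.kruskal(*groups).pvalue > 0.001


class TestDFECorrelation:
    def test_uniform_supply_is_degenerate(self, medium_community):
        _, _, st = medium_community
        r, flag = dfe_correlation([st])
        assert flag and r == 0.0

    def test_nonuniform_supply_gives_positive_correlation(
            self, medium_community_cv):
        _, _, st = medium_community_cv
        r, flag = dfe_correlation([st])
        assert not flag
        assert 0 < r < 1

    def test_budget_only_columns_identical(self, skewed_monoculture):
        # with a pure budget change both fitness columns equal dX: the
        # correlation of identical columns is 1 by convention of pearsonr
        parent, env, state = skewed_monoculture
        m1 = knockout(parent, 1, dX=0.0)
        s_comm = invasion_fitness(state, m1)[1]
        s_mono = monoculture_fitness(parent, env, m1)
        assert s_comm == pytest.approx(s_mono)  # monoculture == community here
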