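import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_toy_tree
from reference import NaiveDiseaseModel

from cflung.geometry import build_tree
from cflung.model import (
    DiseaseState,
    InfectionSite,
    SimParams,
    apply_remodeling,
    apply_treatment,
    check_treatment,
    colonize,
    functional_volume,
    heaviside,
    propagate_overflow,
    sample_colonizations,
    simulate,
    step,
    step_mucus,
    step_scarring,
)

ALL_GENS = dict(bronchiole_gen_min=0)


def fresh_state(tree, params, seed=0):
    return DiseaseState(tree, params, np.random.default_rng(seed))


def single_airway_tree(volume_mm3=1000.0):
    d = 10.0
    L = volume_mm3 / (math.pi * (d / 2) ** 2)
    return build_tree(pd.DataFrame(
        {"generation": [0], "diameter_mm": [d], "length_mm": [L]}))


class TestSwitching:
    @pytest.mark.parametrize("x, expected", [(-3.0, 0), (2.0, 1), (0.0, 1)])
    def test_heaviside(self, x, expected):
        assert heaviside(x) == expected

    def test_mucus_ramp_from_infection_time(self):
        p = SimParams()
        site = InfectionSite(1, t_i=10.0)
        # before the infection time nothing grows
        early = step_mucus(site, False, p, dt=1.0, V_i=1e9, t_now=9.0)
        assert early.M_i == 0.0
        grown = step_mucus(site, False, p, dt=1.0, V_i=1e9, t_now=11.0)
        assert grown.M_i == pytest.approx(p.v_c)

    def test_filled_site_stops_growing(self):
        site = InfectionSite(1, 0.0, M_i=5.0)
        assert step_mucus(site, True, SimParams(), 1.0, 5.0, 1.0).M_i == 5.0

    def test_fill_capped_at_airway_volume(self):
        p = SimParams(v_c=11.0)
        site = InfectionSite(1, 0.0)
        after = step_mucus(site, False, p, dt=1.0, V_i=5.5, t_now=1.0)
        assert after.M_i == 5.5  # half-month of growth then the cap

    def test_scarring_starts_after_delay(self):
        p = SimParams(T_s=5.0, v_s=0.023)
        site = InfectionSite(1, t_i=10.0)
        assert step_scarring(site, False, p, 1.0, t_now=15.0).S_i == 0.0
        s16 = step_scarring(site, False, p, 1.0, t_now=16.0)
        assert s16.S_i == pytest.approx(0.023)

    def test_remodeled_site_scarring_frozen(self):
        site = InfectionSite(1, 0.0, S_i=1.2)
        assert step_scarring(site, True, SimParams(), 1.0, 100.0).S_i == 1.2

    def test_time_from_onset_to_threshold(self):
        p = SimParams()
        assert p.S_star / p.v_s == pytest.approx(43.5, abs=0.05)


class TestColonization:
    def test_zero_probability_never_colonizes(self, toy_tree4):
        p = SimParams(P_c=0.0, **ALL_GENS)
        st_ = fresh_state(toy_tree4, p)
        for _ in range(50):
            step(st_, p, toy_tree4)
        assert st_.n_sites == 0
        assert st_.time == 50.0

    def test_expected_rate_over_healthy_lung(self, default_tree):
        p = SimParams()
        surface = sum(
            default_tree.counts[g] * default_tree.airway_surface_mm2[g]
            for g in range(p.bronchiole_gen_min, 24))
        expected = p.P_c * surface
        st_ = fresh_state(default_tree, p, seed=5)
        draws = [
            sample_colonizations(st_.rng, default_tree, st_.infected_mask,
                                 st_.infected_per_gen, p.P_c, 1.0,
                                 p.bronchiole_gen_min).size
            for _ in range(400)
        ]
        se = np.std(draws) / math.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(expected, abs=4 * se)
        # and the aggregate rate is what the fitted P_c implies: ~70/month
        assert expected == pytest.approx(70, rel=0.20)

    def test_toy_rate_matches_bernoulli_closed_form(self):
        # 3 generations, every airway with lambda = 0.1
        lam = 0.1
        tree = build_tree(pd.DataFrame({
            "generation": [0, 1, 2],
            "diameter_mm": [1.0, 1.0, 1.0],
            "length_mm": [lam / (math.pi * 1e-3)] * 3,
        }))
        P_c = 1e-3
        rng = np.random.default_rng(11)
        mask = np.zeros(8, dtype=bool)
        per_gen = np.zeros(3, dtype=np.int64)
        n = 10_000
        total = sum(
            sample_colonizations(rng, tree, mask, per_gen, P_c, 1.0).size
            for _ in range(n)
        )
        expected = 7 * (1 - math.exp(-lam))
        assert total / n == pytest.approx(expected, rel=0.03)

    def test_aggregated_sampling_equivalent_to_naive(self):
        # chi-square two-sample test on new-site counts, aggregated
        # per-generation sampler vs naive per-airway Bernoulli draws
        tree = make_toy_tree(6)
        P_c = 2e-3
        probs = {
            g: 1 - math.exp(-P_c * tree.airway_surface_mm2[g])
            for g in range(6)
        }
        rng_a = np.random.default_rng(101)
        rng_b = np.random.default_rng(202)
        mask = np.zeros(64, dtype=bool)
        per_gen = np.zeros(6, dtype=np.int64)
        trials = 10_000
        agg = np.array([
            sample_colonizations(rng_a, tree, mask, per_gen, P_c, 1.0).size
            for _ in range(trials)
        ])
        naive = np.array([
            sum(rng_b.random() < probs[int(math.floor(math.log2(k)))]
                for k in range(1, 64))
            for _ in range(trials)
        ])
        top = max(agg.max(), naive.max())
        bins = np.arange(top + 2)
        ca = np.bincount(agg, minlength=top + 1)
        cb = np.bincount(naive, minlength=top + 1)
        # pool sparse tail bins
        keep = (ca + cb) >= 10
        ca = np.append(ca[keep], ca[~keep].sum())
        cb = np.append(cb[keep], cb[~keep].sum())
        _, pvalue, _, _ = stats.chi2_contingency(np.vstack([ca, cb]))
        assert pvalue > 0.01

    def test_placement_uniform_within_generation(self):
        # every airway of a generation must be equally likely to be hit
        tree = make_toy_tree(5)
        P_c = 0.5 / tree.airway_surface_mm2[4]  # lambda=0.5 in generation 4
        rng = np.random.default_rng(7)
        mask = np.zeros(32, dtype=bool)
        per_gen = np.zeros(5, dtype=np.int64)
        hits = np.zeros(32, dtype=int)
        for _ in range(4000):
            new = sample_colonizations(rng, tree, mask, per_gen, P_c, 1.0, gen_min=4)
            hits[new] += 1
        counts = hits[16:32]
        _, pvalue = stats.chisquare(counts)
        assert pvalue > 0.01


class TestOverflowAndTreatment:
    def test_root_fill_infects_both_children(self):
        tree = make_toy_tree(2)
        p = SimParams(P_c=0.0, v_c=1e9, alpha=0.5, **ALL_GENS)
        st_ = fresh_state(tree, p)
        st_.seed_site(1)
        st_.M[0] = tree.airway_volume_mm3[0]
        st_.filled[0] = True
        st_._newly_filled = np.array([1], dtype=np.int64)
        propagate_overflow(st_, tree)
        assert set(st_.sites()) == {1, 2, 3}

    def test_leaf_fill_infects_only_parent(self):
        tree = make_toy_tree(3)
        p = SimParams(P_c=0.0, v_c=1e9, alpha=0.01, **ALL_GENS)
        st_ = fresh_state(tree, p)
        st_.seed_site(5)  # a generation-2 leaf
        step(st_, p, tree)
        assert set(st_.sites()) == {5, 2}

    def test_functional_volume_examples(self, toy_tree4):
        p = SimParams(**ALL_GENS)
        st_ = fresh_state(toy_tree4, p)
        assert functional_volume(st_, toy_tree4) == 1.0
        st_.seed_site(2)
        st_.M[0] = toy_tree4.airway_volume_mm3[1]
        st_.filled[0] = True
        st_._add_blocked(np.array([2]))
        assert functional_volume(st_, toy_tree4) == 0.5
        st2 = fresh_state(toy_tree4, p)
        st2.seed_site(1)
        st2.remodeled[0] = True
        st2._add_blocked(np.array([1]))
        assert functional_volume(st2, toy_tree4) == 0.0

    @pytest.mark.parametrize("V_L, V_L_star, alpha, fires", [
        (0.8, 1.0, 0.9, True),
        (0.95, 1.0, 0.9, False),
        (0.9, 1.0, 0.9, True),  # boundary counts as reached
    ])
    def test_treatment_trigger(self, V_L, V_L_star, alpha, fires):
        assert check_treatment(V_L, V_L_star, alpha) is fires

    def test_alpha_validated(self):
        with pytest.raises(ValueError, match="alpha"):
            check_treatment(0.5, 1.0, 1.5)
        with pytest.raises(ValueError, match="alpha"):
            SimParams(alpha=0.0)

    def test_treatment_clears_undamaged_restores_fvc(self):
        tree = make_toy_tree(3)
        p = SimParams(P_c=0.0, v_c=1e9, T_s=7.0, alpha=0.6, **ALL_GENS)
        st_ = fresh_state(tree, p)
        st_.seed_site(2)
        step(st_, p, tree)  # generation-1 airway fills: half the lung lost
        assert functional_volume(st_, tree) == 1.0  # treatment already fired
        assert st_.n_sites == 0  # unscarred infection fully cleared

    def test_treatment_spares_damaged_sites(self):
        tree = make_toy_tree(3)
        p = SimParams(P_c=0.0, v_c=1e-9, T_s=2.0, v_s=0.1, alpha=0.6,
                      **ALL_GENS)
        st_ = fresh_state(tree, p)
        st_.seed_site(2)
        for _ in range(5):
            step(st_, p, tree)
        assert st_.S[0] == pytest.approx(0.3)  # scarring began at t=2
        apply_treatment(st_, p, tree)
        assert set(st_.sites()) == {2}
        assert st_.t_i[0] == 0.0  # original infection time kept
        before = st_.S[0]
        step(st_, p, tree)
        assert st_.S[0] > before  # scarring continues uninterrupted

    def test_remodeled_subtree_untouched_by_treatment(self, toy_tree4):
        p = SimParams(**ALL_GENS)
        st_ = fresh_state(toy_tree4, p)
        st_.seed_site(2)
        st_.S[0] = 1.0
        apply_remodeling(st_, p, toy_tree4)
        assert st_.R == {2}
        apply_treatment(st_, p, toy_tree4)
        assert st_.R == {2}
        assert functional_volume(st_, toy_tree4) == 0.5


class TestRemodeling:
    def test_threshold_is_inclusive(self, toy_tree4):
        p = SimParams(**ALL_GENS)
        st_ = fresh_state(toy_tree4, p)
        st_.seed_site(1)
        st_.S[0] = 0.999
        apply_remodeling(st_, p, toy_tree4)
        assert st_.R == set()
        st_.S[0] = 1.0
        apply_remodeling(st_, p, toy_tree4)
        assert st_.R == {1}

    def test_closed_form_event_times_single_site(self):
        # an isolated colonization in a huge airway: fill and remodeling
        # times follow the closed forms V/v_c and t_i + T_s + S*/v_s
        tree = single_airway_tree(volume_mm3=1e9)
        p = SimParams(P_c=0.0, v_c=11.0, T_s=7.0, v_s=0.023, alpha=0.5,
                      horizon=60, **ALL_GENS)
        st_ = fresh_state(tree, p)
        st_.seed_site(1)
        expected_remodel = 7.0 + 1.0 / 0.023  # months after t_i = 0
        for m in range(1, 60):
            step(st_, p, tree)
            if st_.remodeled[0]:
                break
        assert m == math.ceil(expected_remodel)
        # interpolating the scar ramp back recovers the exact onset
        onset = st_.time - st_.S[0] / p.v_s
        assert onset == pytest.approx(p.T_s)


class TestStepAndSimulate:
    def test_deterministic_toy_course_matches_reference(self):
        tree = make_toy_tree(4)
        p = SimParams(P_c=0.0, v_c=tree.airway_volume_mm3[1] / 2, T_s=3.0,
                      v_s=0.2, alpha=0.7, **ALL_GENS)
        st_ = fresh_state(tree, p, seed=1)
        ref = NaiveDiseaseModel(tree, p, np.random.default_rng(1))
        st_.seed_site(2)
        ref._infect(2, 0.0)
        for _ in range(20):
            step(st_, p, tree)
            ref.step()
            assert_states_equal(st_, ref)

    def test_random_runs_match_naive_reference(self):
        rng = np.random.default_rng(42)
        mismatches = 0
        for run in range(500):
            n_gen = int(rng.integers(2, 6))
            tree = make_toy_tree(n_gen, d0=float(rng.uniform(4, 12)),
                                 L0=float(rng.uniform(8, 24)))
            p = SimParams(
                P_c=float(rng.uniform(0, 0.02)) / tree.airway_surface_mm2[0],
                v_c=float(rng.uniform(0.5, 50.0)),
                T_s=float(rng.integers(1, 8)),
                v_s=float(rng.uniform(0.01, 0.5)),
                alpha=float(rng.uniform(0.3, 0.95)),
                horizon=25,
                **ALL_GENS,
            )
            seed = int(rng.integers(0, 2 ** 31))
            st_ = fresh_state(tree, p, seed=seed)
            ref = NaiveDiseaseModel(tree, p, np.random.default_rng(seed))
            for _ in range(25):
                step(st_, p, tree)
                ref.step()
            assert_states_equal(st_, ref)
        assert mismatches == 0

    def test_set_consistency_and_conservation_every_step(self):
        tree = make_toy_tree(5)
        p = SimParams(P_c=0.01 / tree.airway_surface_mm2[0], v_c=5.0,
                      T_s=3.0, v_s=0.1, alpha=0.8, **ALL_GENS)
        st_ = fresh_state(tree, p, seed=3)
        for _ in range(40):
            step(st_, p, tree)
            V = tree.airway_volume_mm3[st_.gen]
            assert st_.F == {int(k) for k, m, v in
                             zip(st_.idx, st_.M, V) if m >= v}
            assert st_.R == {int(k) for k, s in zip(st_.idx, st_.S)
                             if s >= p.S_star}
            blocked = st_.F | st_.R
            shut = {k for k in range(1, tree.total_airways + 1)
                    if any(a in blocked for a in tree.ancestors(k))}
            assert st_.O() == shut
            accessible = tree.accessible_alveoli(blocked)
            assert accessible + (tree.n_alveoli - accessible) == tree.n_alveoli
            assert functional_volume(st_, tree) == accessible / tree.n_alveoli

    def test_fvc_non_increasing_without_treatment(self):
        tree = make_toy_tree(6)
        p = SimParams(P_c=0.05 / tree.airway_surface_mm2[5], v_c=20.0,
                      T_s=2.0, v_s=0.2, alpha=1e-9, **ALL_GENS)
        st_ = fresh_state(tree, p, seed=9)
        values = [functional_volume(st_, tree)]
        for _ in range(60):
            step(st_, p, tree)
            values.append(functional_volume(st_, tree))
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_same_seed_bit_identical(self, toy_tree4):
        p = SimParams(P_c=0.05 / toy_tree4.airway_surface_mm2[0], v_c=3.0,
                      horizon=30, seed=77, **ALL_GENS)
        a = simulate(p, toy_tree4, n_replicates=3)
        b = simulate(p, toy_tree4, n_replicates=3)
        assert np.array_equal(a.values, b.values)
        c = simulate(p.with_(seed=78), toy_tree4, n_replicates=3)
        assert not np.array_equal(a.values, c.values)

    def test_trajectory_contract(self, toy_tree4):
        p = SimParams(horizon=40, **ALL_GENS)
        traj = simulate(p, toy_tree4, n_replicates=2)
        assert traj.values.shape == (2, 41)
        assert traj.values[:, 0].tolist() == [100.0, 100.0]
        assert np.all((traj.values >= 0) & (traj.values <= 100))


def assert_states_equal(st_, ref):
    sites = st_.sites()
    assert set(sites) == set(ref.t_i)
    for k, site in sites.items():
        assert site.t_i == ref.t_i[k]
        assert site.M_i == pytest.approx(ref.M[k], abs=1e-9)
        assert site.S_i == pytest.approx(ref.S[k], abs=1e-12)
    assert st_.F == ref.filled
    assert st_.R == ref.remodeled
    assert st_.time == ref.time
    assert st_.V_L_star == pytest.approx(ref.V_L_star, abs=1e-12)
    from cflung.model import functional_volume as fv
    assert fv(st_, st_.tree) == pytest.approx(ref.functional_volume(), abs=1e-12)
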