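"""Tests of the event-driven lineage simulator and its variants."""

import math

import numpy as np
import pytest

from cellsizer.lineage import (
    CycleFailure,
    DivisionRule,
    delete_regulators,
    division_signal,
    draw_threshold,
    equivalent_threshold,
    hazard_sample_division,
    initialize_state,
    partition_at_division,
    power_law_hazard,
    simulate_cycle,
    simulate_lineage,
    swap_promoters,
)
from cellsizer.model import GenomeArrays, rnap_concentration, volume_of
from cellsizer.theory import TheoryInputs, birth_volume, critical_thresholds


class TestInitializeState:
    def test_volume_matches_request(self, default_model):
        genome, params = default_model
        for V0 in (0.1, 0.4, 1.5):
            st = initialize_state(V0, genome, params)
            assert volume_of(st.p, genome, params) == pytest.approx(V0, rel=0.02)

    def test_rnap_density(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        n0 = st.p[genome.role_index("rnap")]
        cn = rnap_concentration(genome, params)
        assert n0 / 0.4 == pytest.approx(cn / params.a, rel=1e-9)

    def test_ribosome_dosage_ratio(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        n0 = st.p[genome.role_index("rnap")]
        r0 = st.p[genome.role_index("ribosome")]
        assert r0 == pytest.approx(10 * n0, rel=1e-9)

    def test_tiny_volume_warns(self, default_model):
        genome, params = default_model
        with pytest.warns(UserWarning):
            initialize_state(1e-8, genome, params)


class TestDrawThreshold:
    def test_zero_width_is_deterministic(self, rng):
        assert draw_threshold(0.7, 0.0, rng) == 0.7

    def test_out_of_range_resets_to_mean(self):
        class FarRng:
            def normal(self, loc, scale):
                return loc + 10 * scale  # always beyond the 3-sigma window

        assert draw_threshold(0.7, 0.1, FarRng()) == 0.7

    def test_moments_match_reset_normal(self, rng):
        draws = np.array([draw_threshold(0.7, 0.1, rng) for _ in range(10**5)])
        assert np.all((draws > 0.6) & (draws < 0.8))
        assert draws.mean() == pytest.approx(0.7, abs=5e-4)
        # reset-to-mean removes ~0.27% of mass from the 3-sigma tails,
        # shrinking the SD by under 2%
        assert draws.std() == pytest.approx(0.1 / 3, rel=0.02)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            draw_threshold(0.05, 0.1, rng)


class TestDivisionSignal:
    def test_reduces_to_simple_ratio(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        rule = DivisionRule(theta=0.6)
        i_a = genome.index("activator")
        i_b = genome.index("inhibitor")
        expect = st.p[i_a] / st.p[i_b] - 0.6
        assert division_signal(st, rule, genome, params) == pytest.approx(expect)

    def test_weighted_panel_hand_value(self):
        from cellsizer.presets import build_default_genome

        genome, params = build_default_genome(
            act_K=[12000.0, 12000.0], inh_K=[1000.0, 1000.0],
            act_weights=[2.0, 0.5], inh_weights=[1.0, 1.0],
        )
        st = initialize_state(0.4, genome, params)
        p = st.p
        ia = [genome.index("act1"), genome.index("act2")]
        ib = [genome.index("inh1"), genome.index("inh2")]
        expect = (2.0 * p[ia[0]] + 0.5 * p[ia[1]]) / (p[ib[0]] + p[ib[1]]) - 0.3
        got = division_signal(st, DivisionRule(theta=0.3), genome, params)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_zero_inhibitor_raises(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        st.p[genome.index("inhibitor")] = 0.0
        with pytest.raises(ZeroDivisionError):
            division_signal(st, DivisionRule(theta=0.6), genome, params)

    def test_alternative_criteria_signs(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        V = volume_of(st.p, genome, params)
        c_act = st.p[genome.index("activator")] / V
        c_inh = st.p[genome.index("inhibitor")] / V
        s_act = division_signal(st, DivisionRule(kind="activator_only",
                                                 theta=c_act / 2), genome, params)
        assert s_act > 0
        s_inh = division_signal(st, DivisionRule(kind="inhibitor_only",
                                                 theta=c_inh / 2), genome, params)
        assert s_inh < 0  # inhibitor still above its threshold: no division yet
        s_and = division_signal(
            st, DivisionRule(kind="and_logic", theta_act=c_act / 2,
                             theta_inh=c_inh * 2), genome, params)
        assert s_and == pytest.approx(min(c_act - c_act / 2, c_inh * 2 - c_inh))


class TestPartition:
    def test_symmetric_halving(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        d = partition_at_division(st, DivisionRule(), genome, params)
        np.testing.assert_allclose(d.m, st.m / 2)
        np.testing.assert_allclose(d.p, st.p / 2)

    def test_asymmetric_volume_fraction(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        d = partition_at_division(st, DivisionRule(gamma=0.4), genome, params)
        # inhibitor mass is negligible, so daughter volume ~ gamma V_d
        assert volume_of(d.p, genome, params) == pytest.approx(
            0.4 * volume_of(st.p, genome, params), rel=1e-6)

    def test_inhibitor_partition_fraction(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        d = partition_at_division(st, DivisionRule(gamma=0.4, eta=0.45),
                                  genome, params)
        i = genome.index("inhibitor")
        assert d.p[i] == pytest.approx(0.45 * st.p[i])
        assert d.m[i] == pytest.approx(0.4 * st.m[i])  # mRNA follows volume

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            DivisionRule(gamma=1.5)
        with pytest.raises(ValueError):
            DivisionRule(eta=0.0)


class TestHazardSampling:
    def test_constant_hazard_is_exponential(self):
        rng = np.random.default_rng(5)
        c = 4.0
        gaps = np.array([
            hazard_sample_division(lambda t: c, 0.5, rng) - 0.5
            for _ in range(4000)
        ])
        assert gaps.mean() == pytest.approx(1 / c, rel=0.06)
        assert gaps.std() == pytest.approx(1 / c, rel=0.08)

    def test_quantile_identity_at_zero(self):
        class ZeroRng:
            def uniform(self):
                return 0.0

        assert hazard_sample_division(lambda t: 1.0, 0.7, ZeroRng()) == 0.7

    def test_huge_hazard_fires_immediately(self):
        rng = np.random.default_rng(0)
        th = hazard_sample_division(lambda t: 1e9, 0.7, rng)
        assert th == pytest.approx(0.7, abs=1e-4)

    def test_unreachable_quantile_raises(self):
        class OneRng:
            def uniform(self):
                return 0.999999

        with pytest.raises(RuntimeError):
            hazard_sample_division(lambda t: 0.0, 0.7, OneRng(), max_span=10.0)


class TestCycleAndLineage:
    def test_deterministic_cycle_is_reproducible(self, default_model):
        genome, params = default_model
        st = initialize_state(0.4, genome, params)
        rule = DivisionRule(theta=0.7)
        r1, s1 = simulate_cycle(st.copy(), rule, genome, params)
        r2, s2 = simulate_cycle(st.copy(), rule, genome, params)
        assert r1 == r2
        np.testing.assert_array_equal(s1.p, s2.p)

    def test_threshold_outside_window_fails(self, default_model, theory_inputs):
        genome, params = default_model
        th1, th2 = critical_thresholds(
            theory_inputs.K_act, theory_inputs.K_inh, theory_inputs.c_n)
        res = simulate_lineage(2, DivisionRule(theta=th2 + 0.02), genome, params,
                               seed=0, burn_in=1)
        assert res.status == "failed_no_division"
        assert res.failed_generation == 0
        res_lo = simulate_lineage(2, DivisionRule(theta=th1 - 0.02), genome,
                                  params, seed=0, burn_in=1)
        assert res_lo.status == "failed_no_division"

    def test_deterministic_fixed_point(self, default_model):
        genome, params = default_model
        res = simulate_lineage(5, DivisionRule(theta=0.8), genome, params,
                               seed=0, burn_in=10)
        vb = res.array("V_b")
        assert res.status == "steady"
        assert vb.std() / vb.mean() < 1e-3

    def test_same_seed_same_records(self, default_model):
        genome, params = default_model
        rule = DivisionRule(theta_bar=0.7, delta_theta=0.1, noise="reset_normal")
        r1 = simulate_lineage(12, rule, genome, params, seed=42, burn_in=3)
        r2 = simulate_lineage(12, rule, genome, params, seed=42, burn_in=3)
        assert [c.theta_k for c in r1.records] == [c.theta_k for c in r2.records]
        assert [c.V_b for c in r1.records] == [c.V_b for c in r2.records]

    def test_volume_continuity_across_division(self, default_model):
        """V_b of the next cycle equals gamma * V_d exactly."""
        genome, params = default_model
        for gamma in (0.5, 0.4):
            res = simulate_lineage(4, DivisionRule(theta=0.7, gamma=gamma),
                                   genome, params, seed=0, burn_in=6)
            vb, vd = res.array("V_b"), res.array("V_d")
            np.testing.assert_allclose(vb[1:], gamma * vd[:-1], rtol=1e-9)

    def test_ratio_dips_before_rising(self, default_model):
        """c_act/c_inh is non-monotonic within a cycle: the minimum occurs
        strictly after birth."""
        genome, params = default_model
        res = simulate_lineage(1, DivisionRule(theta=0.8), genome, params,
                               seed=0, burn_in=10, record_trajectories=True,
                               trajectory_dt=0.002)
        df = res.trajectories
        last = df[df.t > df.t.iloc[-1] - res.records[-1].T_D].reset_index(drop=True)
        ratio = (last.c_act / last.c_inh).values
        imin = int(np.argmin(ratio))
        assert 0 < imin < len(ratio) - 1
        assert ratio[imin] < ratio[0] - 1e-3

    def test_free_rnap_fraction_drops_at_division_but_not_ribosome(self, default_model):
        genome, params = default_model
        res = simulate_lineage(2, DivisionRule(theta=0.8), genome, params,
                               seed=0, burn_in=10, record_trajectories=True,
                               trajectory_dt=0.002)
        df = res.trajectories
        V = df.V.values
        i = int(np.where(V[1:] < 0.6 * V[:-1])[0][-1])
        dFn = abs(df.F_n[i + 1] - df.F_n[i])
        dFr = abs(df.F_r[i + 1] - df.F_r[i])
        assert dFn > 100 * dFr
        assert dFn > 0.05

    def test_perturbation_returns_to_fixed_point(self, default_model):
        """+-10% birth-size perturbations decay within 3 generations."""
        genome, params = default_model
        rule = DivisionRule(theta=0.8)
        base = simulate_lineage(3, rule, genome, params, seed=0, burn_in=10)
        v_fix = base.array("V_b")[-1]
        for factor in (0.9, 1.1):
            st = initialize_state(v_fix * factor, genome, params)
            for k in range(3):
                _, d = simulate_cycle(st, rule, genome, params, index=k)
                st = partition_at_division(d, rule, genome, params)
            assert volume_of(st.p, genome, params) == pytest.approx(
                v_fix, rel=0.01)

    def test_ploidy_doubling_doubles_birth_volume(self, default_model, theory_inputs):
        genome, params = default_model
        rule = DivisionRule(theta=0.7)
        r1 = simulate_lineage(3, rule, genome, params, seed=0, burn_in=10)
        r2 = simulate_lineage(3, rule, genome.with_ploidy(2), params, seed=0,
                              burn_in=10,
                              initial_volume=2 * birth_volume(0.7, theory_inputs))
        assert r2.array("V_b").mean() / r1.array("V_b").mean() == pytest.approx(
            2.0, rel=1e-3)


class TestVariants:
    def test_replication_variant_bookkeeping(self, default_model):
        """Genes double at the trigger and the daughter starts with the
        pre-replication genome, so cycles are periodic and larger than the
        immediate-division model."""
        genome, params = default_model
        base = simulate_lineage(3, DivisionRule(theta=0.7), genome, params,
                                seed=0, burn_in=8)
        rep = simulate_lineage(3, DivisionRule(theta=0.7, replication_delay=1.0),
                               genome, params, seed=0, burn_in=8)
        assert rep.status == "steady"
        vb = rep.array("V_b")
        assert vb.std() / vb.mean() < 1e-3  # periodic steady state
        assert vb.mean() > base.array("V_b").mean()
        assert rep.array("T_D").mean() > base.array("T_D").mean()

    def test_asymmetric_division_matches_theory(self, default_model):
        genome, params = default_model
        ti = TheoryInputs.from_genome(genome, params, gamma=0.4)
        res = simulate_lineage(3, DivisionRule(theta=0.7, gamma=0.4),
                               genome, params, seed=0, burn_in=10)
        assert res.array("V_b").mean() == pytest.approx(
            birth_volume(0.7, ti), rel=0.05)

    def test_nondegradable_inhibitor_cycles(self):
        from cellsizer.presets import build_default_genome

        genome, params = build_default_genome(nondegradable_inhibitor=True)
        assert math.isinf(genome.classes[genome.index("inhibitor")].tau_p)
        res = simulate_lineage(3, DivisionRule(theta=0.0028, alpha=10.0),
                               genome, params, seed=0, burn_in=8,
                               initial_volume=0.18)
        assert res.status == "steady"
        # birth volume grows with the threshold, as in the degradable model
        res2 = simulate_lineage(3, DivisionRule(theta=0.0030, alpha=10.0),
                                genome, params, seed=0, burn_in=8,
                                initial_volume=0.18)
        assert res2.array("V_b").mean() > res.array("V_b").mean()

    def test_heterogeneous_promoters_match_reduced_theory(self):
        """Lognormal bulk MM constants leave the V_b(theta) curve on the
        single-K theory built from the effective (capacity-weighted
        harmonic mean) constant."""
        from cellsizer.presets import build_default_genome

        genome, params = build_default_genome(heterogeneous_bulk=True,
                                              n_bulk_classes=50, seed=4)
        ti = TheoryInputs.from_genome(genome, params)
        for th in (0.45, 0.6, 0.8):
            res = simulate_lineage(3, DivisionRule(theta=th), genome, params,
                                   seed=0, burn_in=10)
            assert res.status == "steady"
            assert res.array("V_b").mean() == pytest.approx(
                birth_volume(th, ti), rel=0.10)

    def test_promoter_swap_widens_size_distribution(self):
        """Swapping the promoters of one activator-inhibitor pair out of ten
        increases the CV of the birth size."""
        from cellsizer.analysis import size_summary
        from cellsizer.presets import build_default_genome

        genome, params = build_default_genome(act_K=[12000.0] * 10,
                                              inh_K=[1000.0] * 10)
        rule = DivisionRule(theta_bar=0.45, delta_theta=0.1, noise="reset_normal")
        wt = simulate_lineage(300, rule, genome, params, seed=21, burn_in=10)
        swapped_genome = swap_promoters(genome, "act1", "inh1")
        sw = simulate_lineage(300, rule, swapped_genome, params, seed=21,
                              burn_in=10)
        assert wt.status == sw.status == "steady"
        assert size_summary(sw.records).cv > 1.2 * size_summary(wt.records).cv

    def test_hazard_variant_imperfect_sizer(self, default_model):
        from scipy.stats import pearsonr

        genome, params = default_model
        res = simulate_lineage(120, DivisionRule(kind="hazard"), genome, params,
                               seed=5, burn_in=10, initial_volume=0.4)
        assert res.status == "steady"
        vb, vd = res.array("V_b"), res.array("V_d")
        r = pearsonr(vb, vd)[0]
        assert r > 0.2  # positive V_d-V_b correlation: imperfect sizer


class TestGenomeEdits:
    def test_delete_then_readd_roundtrip(self, fig_panel_model):
        genome, _ = fig_panel_model
        deleted = delete_regulators(genome, "activator")
        i = deleted.index("activator")
        assert deleted.classes[i].copy_number == 9
        from dataclasses import replace

        restored = type(genome)(
            [replace(c, copy_number=10) if c.label == "activator" else c
             for c in deleted.classes], ploidy=deleted.ploidy)
        assert restored.classes == genome.classes

    def test_cannot_delete_last_regulator(self, default_model):
        genome, _ = default_model
        with pytest.raises(ValueError):
            delete_regulators(genome, "activator")
        with pytest.raises(ValueError):
            delete_regulators(genome, "inhibitor")

    def test_swap_exchanges_only_K(self, default_model):
        genome, _ = default_model
        swapped = swap_promoters(genome, "activator", "inhibitor")
        a0 = genome.classes[genome.index("activator")]
        b0 = genome.classes[genome.index("inhibitor")]
        a1 = swapped.classes[swapped.index("activator")]
        b1 = swapped.classes[swapped.index("inhibitor")]
        assert a1.K_n == b0.K_n and b1.K_n == a0.K_n
        from dataclasses import asdict

        for k, v in asdict(a0).items():
            if k != "K_n":
                assert asdict(a1)[k] == v


class TestEquivalentThreshold:
    def test_equal_counts_identity(self):
        assert equivalent_threshold(10, 10, 0.45) == pytest.approx(0.45)

    def test_hand_value(self):
        assert equivalent_threshold(9, 10, 0.45) == pytest.approx(0.5)

    def test_uniform_weights_cancel(self):
        w = [3.0] * 5
        assert equivalent_threshold(5, 5, 0.6, act_weights=w, inh_weights=w) \
            == pytest.approx(0.6)

    def test_deletion_shifts_threshold(self, fig_panel_model):
        genome, _ = fig_panel_model
        th = equivalent_threshold(10, 10, 0.45)
        th_del = equivalent_threshold(9, 10, 0.45)
        assert th_del == pytest.approx(10 / 9 * th)

    def test_zero_activators_raises(self):
        with pytest.raises(ZeroDivisionError):
            equivalent_threshold(0, 10, 0.45)
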