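"""Spring mechanics: units, force summaries, torque, stiffness, transfer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechanotraj import mechanics as mech
from mechanotraj import synthetic as syn
from mechanotraj.errors import AnalysisError, UnitError


class TestUnits:
    def test_kj_mol_nm_to_pn_constant(self):
        assert mech.convert_force(1.0, "kJ/mol/nm", "pN") == pytest.approx(
            1.66054, abs=1e-5
        )

    @given(
        value=st.floats(-1e6, 1e6, allow_nan=False),
        unit=st.sampled_from(["pN", "nN", "N", "kJ/mol/nm", "kcal/mol/A"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_identity(self, value, unit):
        back = mech.convert_force(
            mech.convert_force(value, unit, "pN"), "pN", unit
        )
        assert back == pytest.approx(value, rel=1e-12, abs=1e-12)

    def test_zero_is_zero_and_unknown_unit_rejected(self):
        assert mech.convert_force(0.0, "N", "pN") == 0.0
        with pytest.raises(UnitError):
            mech.convert_force(1.0, "parsecs", "pN")


def _trace(forces, points=None, times=None):
    forces = np.asarray(forces, dtype=float)
    if times is None:
        times = np.arange(forces.shape[0], dtype=float)
    return mech.ForceTrace(times=times, forces=forces, application_points=points)


class TestReactionForceSummary:
    def test_constant_trace_mean_is_constant_sd_zero(self):
        f = np.tile([[1.0, 2.0, 3.0]], (10, 2, 1))
        s = mech.reaction_force_summary(_trace(f))
        np.testing.assert_allclose(s["per_chain_mean"], [[1, 2, 3], [1, 2, 3]])
        np.testing.assert_allclose(s["per_chain_sd"], 0.0)
        np.testing.assert_allclose(s["net_mean"], [2, 4, 6])

    def test_window_of_length_one_returns_that_sample(self):
        f = np.arange(30.0).reshape(10, 1, 3)
        s = mech.reaction_force_summary(_trace(f), window=(4.0, 4.0))
        np.testing.assert_allclose(s["per_chain_mean"][0], f[4, 0])

    def test_toy_steady_state_net_force_balances_bundle_load(
        self, spring_free_run, spring_push_run
    ):
        # 4 chains x 5 pN compression: net restraint force +20 pN along z.
        # Summaries of both runs share the noise sequence (common random
        # numbers), so their difference isolates the load response.
        t_half = spring_push_run.force_trace.times[
            spring_push_run.force_trace.n_frames // 2
        ]
        window = (t_half, spring_push_run.force_trace.times[-1])
        s_push = mech.reaction_force_summary(spring_push_run.force_trace, window)
        s_free = mech.reaction_force_summary(spring_free_run.force_trace, window)
        net = s_push["net_mean"][2] - s_free["net_mean"][2]
        assert net == pytest.approx(20.0, abs=0.2)


class TestPlanarTorque:
    def test_radial_forces_give_zero_torque(self):
        pts = np.array([[20.0, 0, 0], [0, 20.0, 0], [-20.0, 0, 0], [0, -20.0, 0]])
        forces = np.tile((pts / 10.0)[None, :, :], (5, 1, 1))  # radial, planar
        out = mech.planar_torque(_trace(forces, pts))
        assert out.torque_z_pn_nm == pytest.approx(0.0, abs=1e-12)

    def test_single_tangential_force_torque_arithmetic(self):
        pts = np.array([[20.0, 0.0, 0.0]])  # 2 nm lever arm
        forces = np.tile([[[0.0, 5.0, 0.0]]], (3, 1, 1))  # 5 pN tangential
        out = mech.planar_torque(_trace(forces, pts))
        assert out.torque_z_pn_nm == pytest.approx(10.0)

    def test_mirror_symmetry_flips_sign_exactly(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(scale=15.0, size=(4, 3))
        forces = rng.normal(size=(6, 4, 3))
        direct = mech.planar_torque(_trace(forces, pts))
        mirrored = mech.planar_torque(
            _trace(forces * [1, -1, 1], pts * [1, -1, 1])
        )
        assert mirrored.torque_z_pn_nm == pytest.approx(
            -direct.torque_z_pn_nm, rel=1e-12
        )

    def test_symmetrized_c4_net_planar_force_vanishes(self):
        rng = np.random.default_rng(8)
        pts = np.array([[20.0, 0, 0], [0, 20.0, 0], [-20.0, 0, 0], [0, -20.0, 0]])
        forces = rng.normal(size=(10, 4, 3))
        out = mech.planar_torque(_trace(forces, pts), symmetrize=True)
        sym_mean = out.per_chain_planar_pn
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        for i in range(3):
            np.testing.assert_allclose(rot @ sym_mean[i], sym_mean[i + 1], atol=1e-9)
        # torque itself is invariant under symmetrization
        plain = mech.planar_torque(_trace(forces, pts), symmetrize=False)
        assert out.torque_z_pn_nm == pytest.approx(plain.torque_z_pn_nm)

    def test_achiral_zero_twist_bundle_under_axial_load_gives_zero_torque(self):
        model = syn.SpringModel(twist_per_bead_deg=0.0)
        run = syn.simulate_overdamped(
            model, force_per_chain_pn=-5.0, temperature_K=0.0,
            n_steps=5000, record_every=500, seed=0,
        )
        out = mech.planar_torque(run.force_trace)
        assert out.torque_z_pn_nm == pytest.approx(0.0, abs=1e-9)

    def test_missing_application_points_rejected(self):
        with pytest.raises(AnalysisError):
            mech.planar_torque(_trace(np.zeros((3, 2, 3))))


class TestSpringConstant:
    def test_formula_on_clean_series(self):
        free = np.full(100, 15.0)
        forced = np.full(100, 13.5)
        fit = mech.spring_constant(free, forced, 5.0)
        assert fit.k_pn_per_nm == pytest.approx(5.0 / 1.5)
        assert fit.compressed

    def test_zero_response_rejected(self):
        series = np.full(100, 15.0)
        with pytest.raises(AnalysisError, match="no response"):
            mech.spring_constant(series, series, 5.0)

    def test_non_stationary_forced_series_rejected(self):
        free = np.full(200, 15.0)
        drifting = 15.0 - np.linspace(0.0, 3.0, 200)
        with pytest.raises(AnalysisError, match="non-stationary"):
            mech.spring_constant(free, drifting, 5.0)

    def test_recovery_on_thermal_toy(self, spring_free_run, spring_push_run):
        fit = mech.spring_constant(
            syn.ar_length_series(spring_free_run),
            syn.ar_length_series(spring_push_run),
            5.0,
        )
        assert abs(fit.k_pn_per_nm - 3.0) / 3.0 < 0.15
        assert fit.compressed

    def test_scale_consistency_doubling_force_doubles_dz(self):
        model = syn.SpringModel()
        kwargs = dict(temperature_K=0.0, n_steps=60_000, record_every=1000, seed=0)
        free = syn.ar_length_series(syn.simulate_overdamped(model, **kwargs))
        f1 = mech.spring_constant(
            free,
            syn.ar_length_series(
                syn.simulate_overdamped(model, force_per_chain_pn=-2.0, **kwargs)
            ),
            2.0,
        )
        f2 = mech.spring_constant(
            free,
            syn.ar_length_series(
                syn.simulate_overdamped(model, force_per_chain_pn=-4.0, **kwargs)
            ),
            4.0,
        )
        assert f2.delta_z_nm == pytest.approx(2 * f1.delta_z_nm, rel=5e-3)
        assert f2.k_pn_per_nm == pytest.approx(f1.k_pn_per_nm, rel=5e-3)


class TestBundleComposition:
    def test_sum_of_four_equal_chains(self):
        assert mech.parallel_bundle_constant([3.3] * 4) == pytest.approx(13.2)

    def test_single_spring_identity(self):
        assert mech.parallel_bundle_constant([2.5]) == 2.5

    def test_matches_brute_force_network_reduction(self):
        ks = [2.0, 3.0, 4.0, 5.0]
        # brute force: unit displacement of the common node, sum of restoring forces
        displacement = 1.0
        restoring = sum(k * displacement for k in ks)
        assert mech.parallel_bundle_constant(ks) == pytest.approx(
            restoring / displacement
        )

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(AnalysisError):
            mech.parallel_bundle_constant([])
        with pytest.raises(AnalysisError):
            mech.parallel_bundle_constant([3.0, -1.0])


class TestElasticRangeScan:
    def test_ideal_hookean_fixture_is_elastic(self):
        free = np.full(200, 15.0)
        runs = [(f, np.full(200, 15.0 - f / 3.0)) for f in (1.0, 2.0, 3.0, 4.0, 5.0)]
        out = mech.elastic_range_scan(free, runs)
        assert out["verdict"] == "elastic"
        ks = [row["k_pn_per_nm"] for row in out["table"]]
        np.testing.assert_allclose(ks, 3.0, rtol=1e-12)

    def test_softening_spring_flagged_nonlinear(self):
        free = np.full(200, 15.0)
        # softening: dz grows faster than linearly with force
        runs = [(f, np.full(200, 15.0 - (f / 3.0) * (1 + 0.3 * f))) for f in
                (1.0, 2.0, 3.0, 4.0, 5.0)]
        out = mech.elastic_range_scan(free, runs)
        assert out["verdict"] == "nonlinear"

    def test_single_run_is_undetermined(self):
        free = np.full(100, 15.0)
        out = mech.elastic_range_scan(free, [(5.0, np.full(100, 13.0))])
        assert out["verdict"] == "undetermined"


class TestArrivalOnset:
    def test_identical_traces_give_none(self):
        t = np.arange(0.0, 10.0, 0.01)
        x = np.sin(t)
        assert mech.arrival_onset(t, x, x, baseline_window_ps=2.0) is None

    def test_recovers_imposed_delay_within_one_sample(self):
        times, free, pert = syn.make_delayed_force_traces(8.0, seed=1)
        onset = mech.arrival_onset(times, free, pert, baseline_window_ps=2.0)
        assert onset == pytest.approx(8.0, abs=0.01 + 1e-12)

    def test_invariant_to_common_offset(self):
        times, free, pert = syn.make_delayed_force_traces(8.0, seed=2)
        a = mech.arrival_onset(times, free, pert, baseline_window_ps=2.0)
        b = mech.arrival_onset(times, free + 7.5, pert + 7.5, baseline_window_ps=2.0)
        assert a == b


class TestTransferSpeed:
    def test_formula(self):
        est = mech.transfer_speed([7.5], 15.0)
        assert est.speed_nm_per_ps == pytest.approx(2.0)

    def test_recovers_imposed_speed_over_replicas(self):
        v_true, L = 1.8, 15.0
        onsets = []
        for seed in range(5):
            times, free, pert = syn.make_delayed_force_traces(L / v_true, seed=seed)
            onsets.append(
                mech.arrival_onset(times, free, pert, baseline_window_ps=2.0)
            )
        est = mech.transfer_speed(onsets, L)
        assert abs(est.speed_nm_per_ps - v_true) / v_true < 0.10

    def test_empty_onsets_rejected(self):
        with pytest.raises(AnalysisError):
            mech.transfer_speed([], 15.0)

    def test_force_trace_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        trace = mech.ForceTrace(
            times=np.arange(5.0), forces=rng.normal(size=(5, 4, 3))
        )
        path = tmp_path / "trace.tsv"
        trace.write_tsv(path)
        back = mech.ForceTrace.read_tsv(path, n_chains=4)
        np.testing.assert_allclose(back.forces, trace.forces, atol=1e-12)
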