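"""Synthetic study generator: truth curves, protocol walks, presets."""

import numpy as np
import pytest

import gridrelease as gr
from gridrelease.exceptions import DomainError
from gridrelease.synthetic import (SimulationSpec, fixture_study,
                                   implant_protocol, suspension_protocol,
                                   suspension_spec)


class TestTrueRelease:
    def test_sqrt_scaling_halves_at_quarter_time(self):
        protocol = implant_protocol()
        spec = SimulationSpec("h", "higuchi", {"a": 19.9 / 24.1 / np.sqrt(90)},
                              24.1, protocol, seed=0)
        truth = gr.true_release(spec, np.array([22.5, 90.0]))
        assert truth.cumulative_mg[1] == pytest.approx(19.9, abs=1e-9)
        assert truth.cumulative_mg[0] == pytest.approx(19.9 / 2, abs=1e-9)

    def test_zero_burst_reduces_to_power_law(self):
        protocol = implant_protocol()
        t = np.linspace(0.5, 90, 50)
        blend = SimulationSpec("b", "burst_plus_kp", {"k": 0.02, "n": 0.6},
                               30.0, protocol, seed=0, burst_fraction=0.0)
        kp = SimulationSpec("k", "kp", {"k": 0.02, "n": 0.6},
                            30.0, protocol, seed=0)
        np.testing.assert_allclose(gr.true_release(blend, t).cumulative_mg,
                                   gr.true_release(kp, t).cumulative_mg)

    def test_monotone_and_capped_at_dose(self):
        protocol = implant_protocol()
        t = np.linspace(0.0, 200.0, 1000)
        spec = SimulationSpec("w", "weibull", {"a": 0.05, "b": 0.9},
                              12.0, protocol, seed=0, burst_fraction=0.2)
        truth = gr.true_release(spec, t)
        assert np.all(np.diff(truth.cumulative_mg) >= 0)
        assert np.all(truth.cumulative_mg <= 12.0 + 1e-12)

    def test_spec_validation(self):
        protocol = implant_protocol()
        with pytest.raises(DomainError):
            SimulationSpec("x", "kp", {"k": 1, "n": 1}, 10.0, protocol,
                           seed=0, burst_fraction=1.5)
        with pytest.raises(DomainError):
            SimulationSpec("x", "kp", {"k": 1, "n": 1}, 10.0, protocol,
                           seed=0, recovery=0.0)
        with pytest.raises(DomainError):
            SimulationSpec("x", "nope", {}, 10.0, protocol, seed=0)


class TestSimulateStudy:
    def test_round_trip_identity_without_noise(self, implant_names):
        for i, name in enumerate(implant_names):
            spec = gr.implant_spec(name, seed=i, noise_sigma=0.0,
                                   degradant_fraction=0.0, recovery=1.0)
            events = gr.simulate_study(spec)
            profile = gr.cumulative_release(events, spec.dose_mg, name)
            truth = gr.true_release(spec, profile.times_d)
            np.testing.assert_allclose(profile.cumulative_mg,
                                       truth.cumulative_mg, rtol=0, atol=1e-12)

    def test_degradant_split_preserves_round_trip(self):
        spec = gr.implant_spec("0.8 × 1.2", seed=3, noise_sigma=0.0,
                               degradant_fraction=0.25, recovery=1.0)
        profile = gr.cumulative_release(gr.simulate_study(spec), spec.dose_mg, "u")
        truth = gr.true_release(spec, profile.times_d)
        np.testing.assert_allclose(profile.cumulative_mg, truth.cumulative_mg,
                                   rtol=0, atol=1e-12)

    def test_recovery_scales_reconstruction_linearly(self):
        spec = gr.implant_spec("0.8 × 0.8", seed=4, noise_sigma=0.0,
                               degradant_fraction=0.0, recovery=0.95)
        profile = gr.cumulative_release(gr.simulate_study(spec), spec.dose_mg, "u")
        truth = gr.true_release(spec, profile.times_d)
        np.testing.assert_allclose(profile.cumulative_mg,
                                   0.95 * truth.cumulative_mg, rtol=1e-12)

    def test_seed_determinism(self):
        spec = gr.implant_spec("0.4 × 0.4", seed=9)
        a, b = gr.simulate_study(spec), gr.simulate_study(spec)
        assert a == b
        other = gr.simulate_study(gr.implant_spec("0.4 × 0.4", seed=10))
        assert any(x.conc_parent_mg_l != y.conc_parent_mg_l
                   for x, y in zip(a, other))

    def test_noise_is_unbiased_over_many_seeds(self):
        # mean reconstructed curve over 200 seeds stays within 0.5 % of
        # the (recovery-scaled) truth at every sampling time
        base = gr.implant_spec("0.8 × 0.8", seed=0, noise_sigma=0.02,
                               degradant_fraction=0.0, recovery=1.0)
        total = None
        for seed in range(200):
            spec = gr.implant_spec("0.8 × 0.8", seed=seed, noise_sigma=0.02,
                                   degradant_fraction=0.0, recovery=1.0)
            profile = gr.cumulative_release(gr.simulate_study(spec),
                                            spec.dose_mg, "u")
            total = profile.cumulative_mg if total is None else total + profile.cumulative_mg
        mean_curve = total / 200.0
        truth = gr.true_release(base, profile.times_d).cumulative_mg
        np.testing.assert_allclose(mean_curve, truth, rtol=0.005)


class TestProtocols:
    def test_implant_protocol_structure(self):
        protocol = implant_protocol()
        times = [s.time_h for s in protocol.steps]
        assert times == sorted(times)
        assert protocol.initial_volume_ml == 50.0
        # intraday aliquots are not replaced: volume shrinks
        assert protocol.steps[0].aliquot_ml == 5.0
        assert not protocol.steps[0].full_change
        assert protocol.steps[0].refill_ml == 45.0
        # refills use the weekend volume when the gap spans a Saturday
        refills = {s.refill_ml for s in protocol.steps if s.full_change}
        assert refills == {50.0, 75.0}
        assert times[-1] <= 90 * 24

    def test_suspension_protocol_constant_volume(self):
        protocol = suspension_protocol()
        assert all(s.refill_ml == 1000.0 for s in protocol.steps)
        assert all(not s.full_change for s in protocol.steps)


class TestFixtureStudy:
    def test_nine_implants_bundle(self):
        specs, records, manifest = fixture_study("nine_implants", seed=7)
        assert len(specs) == 9 and len(records) == 9
        assert {s.unit_id for s in specs} == {r.name for r in gr.STUDY_IMPLANTS}
        assert len(manifest["units"]) == 9
        for unit in manifest["units"]:
            assert 0.10 <= unit["burst_fraction"] <= 0.25

    def test_fixture_is_deterministic(self):
        a = fixture_study("nine_implants", seed=3)
        b = fixture_study("nine_implants", seed=3)
        assert a[1] == b[1]
        assert a[2] == b[2]

    def test_release_ordered_by_ssa(self):
        specs, records, _ = fixture_study("nine_implants", seed=1)
        ssa = {r.name: r.ssa_ref_cm2_per_g for r in gr.STUDY_IMPLANTS}
        final = {}
        for spec in specs:
            profile = gr.cumulative_release(records[spec.unit_id],
                                            spec.dose_mg, spec.unit_id)
            final[spec.unit_id] = profile.relative_release[-1]
        order = sorted(final, key=final.get)
        assert sorted(ssa, key=ssa.get)[:3] == order[:3]

    def test_suspension_dissolves_within_100_minutes(self):
        spec = suspension_spec(seed=2, noise_sigma=0.0)
        truth = gr.true_release(spec, np.array([100.0 / 60.0 / 24.0]))
        assert truth.cumulative_mg[0] >= 0.99 * 6.0

    def test_filament_preset(self):
        specs, records, _ = fixture_study("filament", seed=5)
        assert specs[0].dose_mg == pytest.approx(20.0)
        assert specs[0].unit_id == "filament"
        assert len(records["filament"]) > 20
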