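import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grapetx import bloch
from grapetx.objective import (
    CostBreakdown,
    TargetSpec,
    WeightingConfig,
    cost,
    phase_residual,
    roi_weight,
    sample_frequencies,
    target_fa,
    weight_phase,
    weight_profile,
    weight_voxel,
    wrap_phase,
)
from grapetx.waveforms import make_cp_sinc


SPEC = TargetSpec(20.0, 3300.0)
CFG = WeightingConfig(lambda_ph=3.0, lambda_b0=0.02)


class TestTargetFa:
    def test_passband_center(self):
        assert target_fa(0.0, SPEC) == 20.0

    def test_boundary_is_closed(self):
        assert target_fa(SPEC.bandwidth_hz / 2, SPEC) == 20.0
        assert target_fa(-SPEC.bandwidth_hz / 2, SPEC) == 20.0

    def test_stopband_is_zero(self):
        assert target_fa(SPEC.bandwidth_hz, SPEC) == 0.0


class TestWeightProfile:
    def test_passband_plateau(self):
        assert weight_profile(0.0, SPEC, CFG) == 1.0

    def test_zero_at_band_edges(self):
        for f in (SPEC.bandwidth_hz / 2, -SPEC.bandwidth_hz / 2):
            assert weight_profile(f, SPEC, CFG) == pytest.approx(0.0, abs=1e-12)

    def test_stopband_plateau(self):
        assert weight_profile(3 * SPEC.bandwidth_hz, SPEC, CFG) == (
            CFG.stopband_weight
        )

    def test_continuous(self):
        f = np.linspace(-3 * SPEC.bandwidth_hz, 3 * SPEC.bandwidth_hz, 20001)
        w = weight_profile(f, SPEC, CFG)
        assert np.max(np.abs(np.diff(w))) < 5e-3


class TestWeightVoxel:
    def test_zero_db0_reduces_to_profile(self):
        f = np.array([0.0, 1000.0, 4000.0])
        assert np.allclose(weight_voxel(0.0, f, CFG, SPEC),
                           weight_profile(f, SPEC, CFG))

    def test_zero_lambda_ignores_db0(self):
        cfg0 = WeightingConfig(lambda_b0=0.0)
        assert weight_voxel(500.0, 0.0, cfg0, SPEC) == 1.0

    def test_hand_computed_value(self):
        # lambda_b0=0.02, dB0=100 Hz, f=0: 1 + 0.02*100 = 3
        assert weight_voxel(100.0, 0.0, CFG, SPEC) == pytest.approx(3.0)

    def test_sign_of_db0_irrelevant(self):
        assert weight_voxel(-100.0, 0.0, CFG, SPEC) == pytest.approx(3.0)


class TestWeightPhase:
    def test_half_at_step_center(self):
        assert weight_phase(0.2 * SPEC.fa_deg, SPEC, CFG) == pytest.approx(0.5)

    def test_saturates_at_target_fa(self):
        assert weight_phase(SPEC.fa_deg, SPEC, CFG) > 0.99

    def test_suppressed_at_zero_fa(self):
        assert weight_phase(0.0, SPEC, CFG) < 0.05


class TestSampleFrequencies:
    def test_gaussian_sample_std(self):
        fset = sample_frequencies(10_000, ("gaussian", 6600.0), 5, 100.0, 42)
        assert fset.offsets.std() == pytest.approx(6600.0, rel=0.02)

    def test_uniform_draws_inside_interval(self):
        fset = sample_frequencies(500, ("uniform", -6250.0, 6250.0), 3,
                                  100.0, 0)
        assert fset.offsets.min() >= -6250.0
        assert fset.offsets.max() <= 6250.0

    def test_voxels_get_distinct_sets(self):
        fset = sample_frequencies(2, ("gaussian", 1000.0), 4, 100.0, 7)
        assert not np.array_equal(fset.offsets[0], fset.offsets[1])

    def test_deterministic_under_seed(self):
        a = sample_frequencies(10, ("uniform", -1, 1), 3, 100.0, 5)
        b = sample_frequencies(10, ("uniform", -1, 1), 3, 100.0, 5)
        assert np.array_equal(a.offsets, b.offsets)

    def test_pairing(self):
        fset = sample_frequencies(4, ("gaussian", 100.0), 2, 150.0, 1)
        assert np.allclose(fset.paired - fset.offsets, 150.0)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="cauchy"):
            sample_frequencies(4, ("cauchy", 1.0), 2, 100.0, 0)


class TestPhaseResidual:
    def test_linear_phase_gives_zero(self):
        f, df, T = 700.0, 100.0, 3e-3
        phi = lambda x: -np.pi * x * T
        assert phase_residual(phi(f), phi(f + df), df, T) == pytest.approx(0.0)

    def test_constant_phase_gives_minus_one(self):
        # (0 - pi*100*0.003) / (pi*100*0.003) = -1
        assert phase_residual(0.3, 0.3, 100.0, 3e-3) == pytest.approx(-1.0)

    @given(st.integers(-3, 3), st.integers(-3, 3))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_2pi_shifts(self, ka, kb):
        base = phase_residual(0.4, -0.9, 100.0, 3e-3)
        shifted = phase_residual(0.4 + 2 * np.pi * ka, -0.9 + 2 * np.pi * kb,
                                 100.0, 3e-3)
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_zero_delta_f_rejected(self):
        with pytest.raises(ValueError):
            phase_residual(0.0, 0.0, 100.0, 0.0)


class TestRoiWeight:
    def test_reference_values(self):
        assert roi_weight(0.0) == 1.0
        assert roi_weight(10.0) == pytest.approx(np.exp(-1), abs=1e-12)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 80, 50)
        assert np.all(np.diff(roi_weight(d)) < 0)


def brute_force_cost(pulse, cohort, samples, spec, cfg, roi=None):
    """Straight-loop re-implementation of the cohort cost (oracle)."""
    dphi_t = np.pi * samples[0].delta_f_hz * pulse.duration
    mls = ph = 0.0
    n = 0
    for s_idx, (subject, fset) in enumerate(zip(cohort, samples)):
        sens = subject.masked_sens()
        db0 = subject.masked_db0()
        pos = subject.masked_pos()
        for v in range(sens.shape[0]):
            rv = 1.0 if roi is None else roi[s_idx][v]
            for j in range(fset.n_per_voxel):
                f = fset.offsets[v, j]
                st = bloch.simulate_voxel(pulse, sens[v], db0[v], pos[v], f)
                fa, phi = bloch.flip_angle_and_phase(st)
                w = float(weight_voxel(db0[v], f, cfg, spec)) * rv
                tgt = float(target_fa(f, spec))
                mls += w * ((fa - tgt) / spec.fa_deg) ** 2
                n += 1
                if abs(f) <= spec.bandwidth_hz / 2 and cfg.lambda_ph > 0:
                    st2 = bloch.simulate_voxel(
                        pulse, sens[v], db0[v], pos[v], f + fset.delta_f_hz
                    )
                    _, phi2 = bloch.flip_angle_and_phase(st2)
                    rho = float(wrap_phase(phi - phi2 - dphi_t)) / dphi_t
                    ph += float(weight_phase(fa, spec, cfg)) * w * rho**2
    return CostBreakdown(mls / n, ph / n,
                         float(np.sqrt(mls / n + cfg.lambda_ph * ph / n)))


class TestCost:
    def test_matches_brute_force_loop(self, four_voxel_subject):
        spec = TargetSpec(20.0, 2500.0)
        cfg = WeightingConfig(lambda_ph=3.0, lambda_b0=0.02)
        pulse = make_cp_sinc(15.0, 0.6e-3, 4, dt=30e-6)
        samples = [sample_frequencies(4, ("uniform", -3000.0, 3000.0), 2,
                                      100.0, 3)]
        ours = cost(pulse, [four_voxel_subject], samples, spec, cfg)
        oracle = brute_force_cost(pulse, [four_voxel_subject], samples, spec,
                                  cfg)
        assert ours.total == pytest.approx(oracle.total, abs=1e-10)
        assert ours.mls_term == pytest.approx(oracle.mls_term, abs=1e-10)
        assert ours.phase_term == pytest.approx(oracle.phase_term, abs=1e-10)

    def test_roi_weights_enter_cost(self, four_voxel_subject):
        spec = TargetSpec(20.0, 2500.0)
        cfg = WeightingConfig(lambda_ph=3.0, lambda_b0=0.02)
        pulse = make_cp_sinc(15.0, 0.6e-3, 4, dt=30e-6)
        samples = [sample_frequencies(4, ("gaussian", 2000.0), 2, 100.0, 9)]
        roi = [np.array([1.0, 0.5, 0.25, 0.0])]
        ours = cost(pulse, [four_voxel_subject], samples, spec, cfg, roi=roi)
        oracle = brute_force_cost(pulse, [four_voxel_subject], samples, spec,
                                  cfg, roi=roi)
        assert ours.total == pytest.approx(oracle.total, abs=1e-10)

    def test_perfect_response_has_zero_cost(self, four_voxel_subject):
        # zero pulse + all samples in the stopband: FA = target = 0
        # everywhere and no passband pairs, so every residual vanishes
        spec = TargetSpec(20.0, 1000.0)
        cfg = WeightingConfig(lambda_ph=3.0, lambda_b0=0.02)
        pulse = make_cp_sinc(0.0, 0.6e-3, 4, dt=30e-6)
        samples = [sample_frequencies(4, ("uniform", 2000.0, 3000.0), 3,
                                      100.0, 1)]
        c = cost(pulse, [four_voxel_subject], samples, spec, cfg)
        assert c.total == 0.0

    def test_lambda_ph_zero_is_pure_mls(self, four_voxel_subject):
        spec = TargetSpec(20.0, 2500.0)
        pulse = make_cp_sinc(10.0, 0.6e-3, 4, dt=30e-6)
        samples = [sample_frequencies(4, ("gaussian", 2000.0), 2, 100.0, 2)]
        c = cost(pulse, [four_voxel_subject], samples, spec,
                 WeightingConfig(lambda_ph=0.0, lambda_b0=0.02))
        assert c.phase_term == 0.0
        assert c.total == pytest.approx(np.sqrt(c.mls_term))

    def test_symmetric_small_tip_pulse_has_tiny_phase_term(
        self, four_voxel_subject
    ):
        # ties the time-symmetry design choice to the pi*df*T phase model
        spec = TargetSpec(2.0, 2500.0)
        cfg = WeightingConfig(lambda_ph=3.0, lambda_b0=0.0)
        pulse = make_cp_sinc(2.0, 3e-3, 7.5, dt=30e-6)
        samples = [sample_frequencies(4, ("uniform", -1200.0, 1200.0), 3,
                                      100.0, 4)]
        c = cost(pulse, [four_voxel_subject], samples, spec, cfg)
        assert c.phase_term < 1e-4

    def test_adding_a_subject_cannot_decrease_the_sum(self, tiny_cohort):
        # unnormalized sums of squares are monotone in the subject list
        import dataclasses

        spec = TargetSpec(20.0, 2500.0)
        cfg = WeightingConfig(lambda_ph=3.0, lambda_b0=0.02)
        pulse = make_cp_sinc(20.0, 0.6e-3, 4, dt=30e-6)
        subs = []
        for s in tiny_cohort[:2]:
            idx = np.transpose(np.nonzero(s.mask))[:3]
            mask = np.zeros_like(s.mask)
            mask[tuple(idx.T)] = True
            subs.append(dataclasses.replace(s, mask=mask))
        samples = [
            sample_frequencies(3, ("gaussian", 3000.0), 2, 100.0, 10 + i)
            for i in range(2)
        ]
        c1 = cost(pulse, subs[:1], samples[:1], spec, cfg)
        c2 = cost(pulse, subs, samples, spec, cfg)
        n1, n2 = 6, 12
        sum1 = (c1.mls_term + cfg.lambda_ph * c1.phase_term) * n1
        sum2 = (c2.mls_term + cfg.lambda_ph * c2.phase_term) * n2
        assert sum2 >= sum1 - 1e-12
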