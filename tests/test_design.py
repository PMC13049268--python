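import dataclasses

import numpy as np
import pytest

from grapetx.constants import REF_SENS_HZ_PER_V
from grapetx.design import (
    DesignConfig,
    PulseDesignModel,
    apply_shim,
    b1_shim_baseline,
    design_roi,
    fa_nrmse,
)
from grapetx.fields import SubjectFieldMap
from grapetx.objective import TargetSpec, WeightingConfig
from grapetx.waveforms import check_limits, write_pulse


def small_config(**overrides):
    kwargs = dict(
        target=TargetSpec(20.0, 2500.0),
        weights=WeightingConfig(lambda_ph=3.0, lambda_b0=0.01),
        duration_s=3e-3,
        dt_coarse_s=150e-6,
        dt_fine_s=50e-6,
        n_freq_per_voxel=2,
        max_iter=25,
        seed=5,
        max_voxels_per_subject=25,
    )
    kwargs.update(overrides)
    return DesignConfig(**kwargs)


def single_voxel_subject():
    shape = (3, 3, 3)
    sens = np.full((8,) + shape, REF_SENS_HZ_PER_V / 8, dtype=complex)
    mask = np.zeros(shape, dtype=bool)
    mask[1, 1, 1] = True
    return SubjectFieldMap(sens * mask, np.zeros(shape), mask, 5.0,
                           np.array([-5.0, -5.0, -5.0]), "unitvox")


class TestGradient:
    def test_adjoint_gradient_matches_finite_differences(self, tiny_subject):
        cfg = small_config(duration_s=0.6e-3, dt_coarse_s=60e-6,
                           dt_fine_s=30e-6, max_voxels_per_subject=6)
        model = PulseDesignModel([tiny_subject], cfg)
        rng = np.random.default_rng(0)
        n_par = 2 * 8 * model._nh + 3 * model._nh
        x = rng.normal(0, 0.5, n_par)

        pulse = model._unpack(x)
        _, d_rf, d_grad, _ = model._cost_and_grad(pulse)
        grad = np.concatenate(
            [
                model._fold(d_rf).real.ravel() * model._V_SCALE,
                model._fold(d_rf).imag.ravel() * model._V_SCALE,
                model._fold(d_grad).ravel() * model._G_SCALE,
            ]
        )
        eps = 1e-6
        idx = rng.choice(n_par, 20, replace=False)
        for i in idx:
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            cp = model._cost_and_grad(model._unpack(xp))[0]
            cm = model._cost_and_grad(model._unpack(xm))[0]
            fd = (cp - cm) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-10)


class TestFit:
    def test_single_unit_voxel_never_worse_than_cp_init(self):
        cfg = small_config(max_iter=15)
        model = PulseDesignModel([single_voxel_subject()], cfg)
        res = model.fit()
        assert res.final_cost <= res.init_cost + 1e-12
        assert res.limit_report.passed

    def test_designed_pulse_respects_all_limits(self, tiny_subject):
        cfg = small_config(target=TargetSpec(90.0, 2500.0), max_iter=30)
        res = PulseDesignModel([tiny_subject], cfg).fit()
        rep = check_limits(res.pulse, cfg.limits, cfg.impedance_ohm)
        assert rep.passed
        assert res.final_cost <= res.init_cost

    def test_cost_trace_starts_at_init_cost(self, tiny_subject):
        res = PulseDesignModel([tiny_subject], small_config(max_iter=5)).fit()
        assert res.cost_trace[0] == pytest.approx(res.init_cost)

    def test_deterministic_given_config_and_cohort(self, tiny_subject):
        cfg = small_config(max_iter=10)
        a = PulseDesignModel([tiny_subject], cfg).fit()
        b = PulseDesignModel([tiny_subject], cfg).fit()
        assert np.array_equal(a.pulse.rf, b.pulse.rf)
        assert np.array_equal(a.pulse.grad, b.pulse.grad)

    def test_improves_nrmse_on_cohort(self, tiny_cohort):
        cfg = small_config(target=TargetSpec(90.0, 2500.0),
                           dt_coarse_s=100e-6, max_iter=60,
                           max_voxels_per_subject=40)
        res = PulseDesignModel(tiny_cohort[:2], cfg).fit()
        nrmse0 = res.nrmse_per_subject(res.init_pulse).mean()
        nrmse1 = res.nrmse_per_subject().mean()
        assert nrmse1 < nrmse0

    def test_summary_mentions_cost_and_limits(self, tiny_subject):
        res = PulseDesignModel([tiny_subject], small_config(max_iter=5)).fit()
        text = res.summary()
        assert "cost" in text and "limit check" in text


class TestDesignRoi:
    def test_every_second_slice_reuse(self, tiny_subject):
        cfg = small_config(max_iter=5, max_voxels_per_subject=15)
        base = PulseDesignModel([tiny_subject], cfg).fit()
        results = design_roi([tiny_subject], cfg, [-20.0, -10.0, 0.0, 10.0],
                             base=base)
        assert len(results) == 4
        assert results[1] is results[0]
        assert results[3] is results[2]
        assert results[2] is not results[0]

    def test_roi_weights_decay_from_slice_center(self, tiny_subject):
        cfg = small_config(max_voxels_per_subject=None)
        model = PulseDesignModel([tiny_subject], cfg, roi_centers_mm=[0.0])
        d = np.abs(tiny_subject.masked_pos()[:, cfg.sel_axis])
        assert np.allclose(model.roi_weights[0], np.exp(-d / 10.0))

    def test_roi_design_not_worse_than_whole_volume_on_its_slice(
        self, tiny_subject
    ):
        cfg = small_config(max_iter=15, max_voxels_per_subject=20)
        base = PulseDesignModel([tiny_subject], cfg).fit()
        results = design_roi([tiny_subject], cfg, [0.0], base=base)
        roi_model = PulseDesignModel([tiny_subject], cfg, roi_centers_mm=[0.0])
        c_roi = roi_model.cost_breakdown(results[0].pulse_coarse).total
        c_whole = roi_model.cost_breakdown(base.pulse_coarse).total
        assert c_roi <= c_whole + 1e-9

    def test_empty_position_list_rejected(self, tiny_subject):
        with pytest.raises(ValueError):
            design_roi([tiny_subject], small_config(), [])


class TestB1Shim:
    def test_single_channel_weight_is_inverse_mean_magnitude(self):
        shape = (3, 3, 3)
        rng = np.random.default_rng(3)
        mag = rng.uniform(0.5, 2.0, shape)
        mask = np.ones(shape, dtype=bool)
        sub = SubjectFieldMap(mag[None, :].astype(complex), np.zeros(shape),
                              mask, 5.0, np.zeros(3), "onech")
        w = b1_shim_baseline(sub, fa_target=20.0)
        expected = REF_SENS_HZ_PER_V / mag.mean()
        assert abs(w[0]) == pytest.approx(expected, rel=1e-6)

    def test_shim_beats_cp_on_opposed_phase_toy(self):
        # two channels with opposed phase ramps: CP interferes destructively,
        # the MLS shim must reduce the coefficient of variation
        shape = (8, 1, 1)
        x = np.linspace(-1, 1, 8).reshape(shape)
        sens = np.stack([np.exp(2j * x), np.exp(-2j * x)]) + 0j
        mask = np.ones(shape, dtype=bool)
        sub = SubjectFieldMap(sens, np.zeros(shape), mask, 5.0,
                              np.zeros(3), "toy")
        a = sub.masked_sens()
        w = b1_shim_baseline(sub, fa_target=20.0)
        cp = np.abs(a.sum(axis=1))
        shimmed = np.abs(a @ w)
        assert shimmed.std() / shimmed.mean() < cp.std() / cp.mean()

    def test_shim_objective_not_worse_than_cp(self, tiny_subject):
        a = tiny_subject.masked_sens()
        w = b1_shim_baseline(tiny_subject, fa_target=20.0)
        target = np.abs(a.sum(axis=1)).mean()
        # compare at matched mean magnitude (the shim is scale-normalized)
        shim = np.abs(a @ w)
        shim = shim * target / shim.mean()
        obj_shim = np.sum((shim - target) ** 2)
        obj_cp = np.sum((np.abs(a.sum(axis=1)) - target) ** 2)
        assert obj_shim <= obj_cp * (1 + 1e-9)

    def test_shimmed_cp_sinc_hits_target_on_average(self, tiny_subject):
        from grapetx import bloch
        from grapetx.waveforms import make_cp_sinc

        w = b1_shim_baseline(tiny_subject, fa_target=20.0)
        pulse = apply_shim(make_cp_sinc(20.0, 3e-3, 10), w)
        sens = tiny_subject.masked_sens()
        m = bloch.simulate_spins(
            pulse, sens, np.zeros(len(sens)), tiny_subject.masked_pos(),
            np.zeros(len(sens)),
        )
        fa, _ = bloch.fa_phase_from_m(m)
        assert fa.mean() == pytest.approx(20.0, rel=0.05)

    def test_all_zero_sensitivities_rejected(self):
        shape = (2, 2, 2)
        sub = SubjectFieldMap(np.zeros((2,) + shape, complex),
                              np.zeros(shape), np.ones(shape, bool), 5.0,
                              np.zeros(3), "zero")
        with pytest.raises(ValueError):
            b1_shim_baseline(sub, fa_target=20.0)


class TestFaNrmse:
    def test_perfect_flip_angles(self):
        assert fa_nrmse([20.0, 20.0, 20.0], 20.0) == 0.0

    def test_hand_computed_value(self):
        assert fa_nrmse([18.0, 22.0], 20.0) == pytest.approx(10.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(8)
        fa = rng.uniform(10, 30, 50)
        assert fa_nrmse(fa, 20.0) == pytest.approx(
            fa_nrmse(rng.permutation(fa), 20.0)
        )


class TestDesignConfig:
    def test_from_flat_dict(self):
        cfg = DesignConfig.from_dict(
            {
                "fa_target_deg": 20.0,
                "bandwidth_hz": 3300.0,
                "lambda_ph": 3.0,
                "lambda_b0": 0.02,
                "delta_f_hz": 100.0,
                "n_freq_per_voxel": 5,
                "freq_dist": ["gaussian", 6600.0],
                "duration_s": 3e-3,
                "dt_coarse_s": 30e-6,
                "seed": 11,
            }
        )
        assert cfg.target.bandwidth_hz == 3300.0
        assert cfg.freq_dist == ("gaussian", 6600.0)
        assert cfg.n_freq_per_voxel == 5
        assert cfg.seed == 11

    def test_uneven_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(duration_s=3e-3, dt_coarse_s=7e-6)

    def test_coarse_finer_than_fine_rejected(self):
        with pytest.raises(ValueError):
            DesignConfig(dt_coarse_s=5e-6, dt_fine_s=10e-6)
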