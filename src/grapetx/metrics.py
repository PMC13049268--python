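"""Evaluation reports: per-subject excitation quality of a designed pulse.

Mirrors the quantities a pulse-design study tabulates per subject: passband
flip-angle mean/std and NRMSE at the slice/slab center frequency, the
phase-sensitive slice integral, pulse energy and the hardware-limit check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bloch
from .constants import DEFAULT_IMPEDANCE_OHM, GAMMA_BAR_HZ_PER_UT
from .design import fa_nrmse
from .objective import TargetSpec
from .waveforms import HardwareLimits, PulseWaveforms, check_limits, pulse_energy

__all__ = ["EvaluationReport", "evaluate_pulse", "measure_fwhm"]


def measure_fwhm(freqs_hz: np.ndarray, response: np.ndarray) -> float:
    """Full width at half maximum of a (box-like) response curve.

    Width between the outermost half-maximum crossings, with linear
    interpolation between samples.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    response = np.asarray(response, dtype=float)
    half = response.max() / 2.0
    above = np.nonzero(response >= half)[0]
    if above.size == 0:
        return 0.0
    lo, hi = above[0], above[-1]
    f_lo = freqs_hz[lo]
    if lo > 0:
        f_lo = np.interp(half, [response[lo - 1], response[lo]],
                         [freqs_hz[lo - 1], freqs_hz[lo]])
    f_hi = freqs_hz[hi]
    if hi < freqs_hz.size - 1:
        f_hi = np.interp(half, [response[hi + 1], response[hi]],
                         [freqs_hz[hi + 1], freqs_hz[hi]])
    return float(f_hi - f_lo)


@dataclass
class EvaluationReport:
    """Per-subject rows plus cohort aggregates (recomputable from rows)."""

    rows: list = field(default_factory=list)
    energy_mj: float = 0.0
    limits_passed: bool = True

    @property
    def aggregates(self) -> dict:
        keys = ("fa_mean_deg", "fa_std_deg", "fa_nrmse_pct",
                "slice_integral_mean", "slice_integral_std")
        return {
            k: float(np.mean([r[k] for r in self.rows]))
            for k in keys if all(k in r for r in self.rows)
        }

    def to_text(self) -> str:
        cols = list(self.rows[0].keys())
        lines = ["\t".join(cols)]
        for r in self.rows:
            lines.append("\t".join(
                str(r[c]) if isinstance(r[c], str) else f"{r[c]:.6g}"
                for c in cols
            ))
        agg = self.aggregates
        lines.append("# aggregates: " + ", ".join(
            f"{k}={v:.6g}" for k, v in agg.items()
        ))
        lines.append(f"# energy_mj={self.energy_mj:.6g} "
                     f"limits_passed={self.limits_passed}")
        return "\n".join(lines)


def evaluate_pulse(
    pulse: PulseWaveforms,
    cohort,
    target: TargetSpec,
    limits: HardwareLimits | None = None,
    slice_thickness_mm: float | None = None,
    n_profile_voxels: int = 32,
    profile_cfg: bloch.ProfileEvalConfig | None = None,
    impedance_ohm: float = DEFAULT_IMPEDANCE_OHM,
    seed: int = 0,
) -> EvaluationReport:
    """Bloch-evaluate a pulse on every subject of a cohort.

    Flip angles are simulated at f = 0 (the slice/slab center) for every
    masked voxel. If a slice thickness is given, the slice integral is
    additionally computed on ``n_profile_voxels`` randomly chosen voxels
    per subject with the selection gradient G = BW / (gamma_bar * thickness)
    and the default 3000-spin, 6 mm profile arrangement.
    """
    report = EvaluationReport()
    report.energy_mj = pulse_energy(pulse, impedance_ohm)
    if limits is not None:
        report.limits_passed = check_limits(pulse, limits, impedance_ohm).passed
    rng = np.random.default_rng(seed)
    if slice_thickness_mm is not None and profile_cfg is None:
        g_sel = target.bandwidth_hz / (GAMMA_BAR_HZ_PER_UT * slice_thickness_mm)
        profile_cfg = bloch.ProfileEvalConfig(sel_grad_mt_m=g_sel)
    for subject in cohort:
        sens = subject.masked_sens()
        db0 = subject.masked_db0()
        pos = subject.masked_pos()
        m = bloch.simulate_spins(pulse, sens, db0, pos, np.zeros(len(db0)))
        fa, _ = bloch.fa_phase_from_m(m)
        row = {
            "subject_id": subject.subject_id,
            "fa_mean_deg": float(fa.mean()),
            "fa_std_deg": float(fa.std()),
            "fa_nrmse_pct": fa_nrmse(fa, target.fa_deg),
        }
        if profile_cfg is not None:
            n_eval = min(n_profile_voxels, len(db0))
            idx = rng.choice(len(db0), n_eval, replace=False)
            integrals = []
            spacing = profile_cfg.length_mm / (profile_cfg.n_spins - 1)
            for v in idx:
                prof = bloch.slice_profile(
                    pulse, sens[v][None, :], db0[v], pos[v], profile_cfg
                )
                # normalize: unit |Mxy| across the nominal thickness -> 1
                integrals.append(
                    bloch.slice_integral(prof, spacing)
                    / (target.bandwidth_hz
                       / (GAMMA_BAR_HZ_PER_UT * profile_cfg.sel_grad_mt_m))
                )
            row["slice_integral_mean"] = float(np.mean(integrals))
            row["slice_integral_std"] = float(np.std(integrals))
        report.rows.append(row)
    return report
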