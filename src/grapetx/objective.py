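"""Cost function for spectrally selective pulse design.

The design target is a rectangular spectral flip-angle profile: FA_T inside
the passband |f| <= BW_T/2, zero outside. The cost over a cohort is

    c = sqrt( (1/N) * [ sum_{s,v,f} roi * w(dB0, f) * ((FA - FA_T(f))/FA_T(0))^2
              + lambda_ph * sum_{passband} roi * w_ph(FA) * w(dB0, f) * rho^2 ] )

where rho is the phase-consistency residual: the phase difference between
the responses at f and at a slightly shifted f + df must match the free-
precession value pi*df*T expected of a linear-phase (time-symmetric) pulse,

    rho = wrap( phi(f) - phi(f+df) - pi*df*T ) / (pi*df*T).

w(dB0, f) = w_profile(f) * (1 + lambda_b0 * |dB0|) up-weights voxels with
strong off-resonance; w_profile decays to zero at the passband/stopband
boundaries (raised-cosine flanks, configurable stopband plateau) so the
unavoidable transition band does not dominate the quadratic cost; w_ph is a
tanh step centered at 20% of the target flip angle that disables the phase
term where the flip angle (and hence the phase) is ill-defined. N is the
total number of (subject, voxel, frequency) samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bloch
from .waveforms import PulseWaveforms

__all__ = [
    "TargetSpec",
    "WeightingConfig",
    "FrequencySampleSet",
    "CostBreakdown",
    "target_fa",
    "weight_profile",
    "weight_voxel",
    "weight_phase",
    "weight_phase_derivative",
    "sample_frequencies",
    "phase_residual",
    "roi_weight",
    "cost",
]


@dataclass
class TargetSpec:
    """Rectangular spectral target: flip angle (deg) and bandwidth (Hz)."""

    fa_deg: float
    bandwidth_hz: float

    def __post_init__(self) -> None:
        if self.fa_deg <= 0:
            raise ValueError("target flip angle must be positive")
        if self.bandwidth_hz <= 0:
            raise ValueError("target bandwidth must be positive")


@dataclass
class WeightingConfig:
    """Weighting and phase-term parameters of the cost function.

    ``transition_width_hz`` is the full width of each raised-cosine flank of
    w_profile (default 0.3 * BW_T, resolved lazily); ``wph_steepness`` the
    tanh slope in 1/deg (default 10 / FA_T, saturating within +-20% of FA_T).
    """

    lambda_ph: float = 3.0
    lambda_b0: float = 0.02
    delta_f_hz: float = 100.0
    transition_width_hz: float | None = None
    stopband_weight: float = 0.5
    wph_steepness: float | None = None
    wph_center_frac: float = 0.20

    def __post_init__(self) -> None:
        if self.lambda_ph < 0 or self.lambda_b0 < 0:
            raise ValueError("lambda_ph and lambda_b0 must be non-negative")
        if self.delta_f_hz <= 0:
            raise ValueError("delta_f_hz must be positive")

    def transition_width(self, spec: TargetSpec) -> float:
        tw = (0.3 * spec.bandwidth_hz if self.transition_width_hz is None
              else self.transition_width_hz)
        if not 0 < tw < spec.bandwidth_hz:
            raise ValueError("transition width must lie in (0, BW_T)")
        return tw

    def steepness(self, spec: TargetSpec) -> float:
        return (10.0 / spec.fa_deg if self.wph_steepness is None
                else self.wph_steepness)


@dataclass
class FrequencySampleSet:
    """Per-voxel random frequency offsets, each paired with f + delta_f."""

    offsets: np.ndarray  # (n_voxels, n_per_voxel), Hz
    delta_f_hz: float
    distribution: tuple
    seed: int

    @property
    def n_voxels(self) -> int:
        return self.offsets.shape[0]

    @property
    def n_per_voxel(self) -> int:
        return self.offsets.shape[1]

    @property
    def paired(self) -> np.ndarray:
        return self.offsets + self.delta_f_hz


@dataclass
class CostBreakdown:
    """Normalized MLS and phase terms; total c = sqrt(mls + lambda_ph*phase)."""

    mls_term: float
    phase_term: float
    total: float


def target_fa(f, spec: TargetSpec):
    """Rectangular target profile: FA_T for |f| <= BW_T/2 (closed), else 0."""
    f = np.asarray(f, dtype=float)
    return np.where(np.abs(f) <= spec.bandwidth_hz / 2, spec.fa_deg, 0.0)


def weight_profile(f, spec: TargetSpec, cfg: WeightingConfig):
    """Frequency weighting: passband plateau 1, zero at +-BW_T/2, stopband
    plateau ``cfg.stopband_weight``; raised-cosine flanks, continuous."""
    f = np.abs(np.asarray(f, dtype=float))
    edge = spec.bandwidth_hz / 2
    half_tw = cfg.transition_width(spec) / 2
    w = np.ones_like(f)
    # passband flank: 1 -> 0 over [edge - half_tw, edge]
    u = np.clip((f - (edge - half_tw)) / half_tw, 0.0, 1.0)
    w = 0.5 * (1 + np.cos(np.pi * u))
    # stopband flank: 0 -> plateau over [edge, edge + half_tw]
    v = np.clip((f - edge) / half_tw, 0.0, 1.0)
    stop = cfg.stopband_weight * 0.5 * (1 - np.cos(np.pi * v))
    return np.where(f <= edge, w, stop)


def weight_voxel(db0_hz, f, cfg: WeightingConfig, spec: TargetSpec):
    """w(dB0, f) = w_profile(f) * (1 + lambda_b0 * |dB0| in Hz)."""
    db0_hz = np.asarray(db0_hz, dtype=float)
    return weight_profile(f, spec, cfg) * (1 + cfg.lambda_b0 * np.abs(db0_hz))


def weight_phase(fa_deg, spec: TargetSpec, cfg: WeightingConfig):
    """tanh step in the simulated flip angle, centered at 20% of FA_T."""
    fa_deg = np.asarray(fa_deg, dtype=float)
    k = cfg.steepness(spec)
    return 0.5 * (1 + np.tanh(k * (fa_deg - cfg.wph_center_frac * spec.fa_deg)))


def weight_phase_derivative(fa_deg, spec: TargetSpec, cfg: WeightingConfig):
    """d w_ph / d FA, needed by the analytic cost gradient."""
    fa_deg = np.asarray(fa_deg, dtype=float)
    k = cfg.steepness(spec)
    return 0.5 * k / np.cosh(k * (fa_deg - cfg.wph_center_frac * spec.fa_deg)) ** 2


def sample_frequencies(
    mask,
    dist: tuple,
    n_per_voxel: int,
    delta_f_hz: float,
    seed: int,
) -> FrequencySampleSet:
    """Draw each voxel's unique frequency-offset set, deterministically.

    ``mask`` is a boolean array (its count is used) or an integer voxel
    count. ``dist`` is ("gaussian", sigma_hz) or ("uniform", lo_hz, hi_hz).
    """
    if n_per_voxel < 1:
        raise ValueError("n_per_voxel must be >= 1")
    n_voxels = int(mask) if np.isscalar(mask) else int(np.asarray(mask).sum())
    rng = np.random.default_rng(seed)
    name = dist[0].lower()
    if name == "gaussian":
        offsets = rng.normal(0.0, dist[1], size=(n_voxels, n_per_voxel))
    elif name == "uniform":
        offsets = rng.uniform(dist[1], dist[2], size=(n_voxels, n_per_voxel))
    else:
        raise ValueError(f"unknown frequency distribution {dist[0]!r}")
    return FrequencySampleSet(offsets, delta_f_hz, tuple(dist), seed)


def wrap_phase(x):
    """Wrap to (-pi, pi]."""
    return np.arctan2(np.sin(x), np.cos(x))


def phase_residual(phi_f, phi_fd, delta_f_hz: float, duration_s: float):
    """Normalized deviation from the free-precession phase relation.

    wrap(phi(f) - phi(f+df) - pi*df*T) / (pi*df*T); zero for an exactly
    linear-phase response phi(f) = -pi*f*T.
    """
    dphi_t = np.pi * delta_f_hz * duration_s
    if dphi_t == 0:
        raise ValueError("delta_f * duration must be nonzero")
    return wrap_phase(np.asarray(phi_f) - np.asarray(phi_fd) - dphi_t) / dphi_t


def roi_weight(distance_mm, decay_mm: float = 10.0):
    """Slice-ROI weighting exp(-d / 10 mm)."""
    distance_mm = np.asarray(distance_mm, dtype=float)
    if np.any(distance_mm < 0):
        raise ValueError("distance must be non-negative")
    return np.exp(-distance_mm / decay_mm)


def cost(
    pulse: PulseWaveforms,
    cohort,
    samples,
    spec: TargetSpec,
    cfg: WeightingConfig,
    roi=None,
) -> CostBreakdown:
    """Evaluate the universal cost of a pulse over a cohort.

    ``samples`` is one :class:`FrequencySampleSet` per subject, covering the
    subject's masked voxels in mask order; ``roi`` (optional) one weight
    array per subject, same order. Flip angles and phases come from Bloch
    simulations at each sampled offset and, for passband samples, at the
    paired offset f + delta_f.
    """
    if len(samples) != len(cohort):
        raise ValueError("need one frequency sample set per subject")
    duration = pulse.duration
    dphi_t = np.pi * samples[0].delta_f_hz * duration
    mls_sum = 0.0
    phase_sum = 0.0
    n_terms = 0
    for s_idx, (subject, fset) in enumerate(zip(cohort, samples)):
        sens = subject.masked_sens()
        db0 = subject.masked_db0()
        pos = subject.masked_pos()
        nv = sens.shape[0]
        if fset.n_voxels != nv:
            raise ValueError(
                f"sample set for subject {s_idx} covers {fset.n_voxels} voxels, "
                f"mask has {nv}"
            )
        roi_w = np.ones(nv) if roi is None else np.asarray(roi[s_idx], dtype=float)
        nf = fset.n_per_voxel
        f = fset.offsets.ravel()  # voxel-major
        vidx = np.repeat(np.arange(nv), nf)
        m = bloch.simulate_spins(pulse, sens[vidx], db0[vidx], pos[vidx], f)
        fa, phase = bloch.fa_phase_from_m(m)
        w = weight_voxel(db0[vidx], f, cfg, spec) * roi_w[vidx]
        mls_sum += float(np.sum(w * ((fa - target_fa(f, spec)) / spec.fa_deg) ** 2))
        n_terms += f.size

        in_pass = np.abs(f) <= spec.bandwidth_hz / 2
        if cfg.lambda_ph > 0 and in_pass.any():
            fp = f[in_pass] + fset.delta_f_hz
            vp = vidx[in_pass]
            mp = bloch.simulate_spins(pulse, sens[vp], db0[vp], pos[vp], fp)
            _, phase_p = bloch.fa_phase_from_m(mp)
            rho = wrap_phase(phase[in_pass] - phase_p - dphi_t) / dphi_t
            phase_sum += float(
                np.sum(weight_phase(fa[in_pass], spec, cfg) * w[in_pass] * rho**2)
            )
    mls = mls_sum / n_terms
    ph = phase_sum / n_terms
    return CostBreakdown(mls, ph, float(np.sqrt(mls + cfg.lambda_ph * ph)))
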