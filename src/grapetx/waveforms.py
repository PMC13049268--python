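"""Multi-channel RF + gradient waveform container and operations.

A pulse is a set of complex per-channel voltage samples (Nc x Nt) plus a
3-axis gradient waveform (3 x Nt) on a uniform time grid. Samples live on a
midpoint grid: sample n represents the interval [n*dt, (n+1)*dt) and its
nominal time is (n + 1/2)*dt, which makes time-mirroring exact for any Nt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_IMPEDANCE_OHM, REF_SENS_HZ_PER_V

__all__ = [
    "PulseWaveforms",
    "HardwareLimits",
    "LimitReport",
    "make_cp_sinc",
    "resample_linear",
    "pulse_energy",
    "check_limits",
    "symmetrize",
    "extract_half",
    "write_pulse",
    "read_pulse",
]


@dataclass
class PulseWaveforms:
    """Per-channel complex RF voltages and 3-axis gradients on a uniform grid.

    Parameters
    ----------
    rf : ndarray, complex, shape (n_channels, n_samples)
        Channel voltages in volts.
    grad : ndarray, float, shape (3, n_samples)
        Gradient amplitudes in mT/m.
    dt : float
        Sample duration in seconds.
    """

    rf: np.ndarray
    grad: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.rf = np.atleast_2d(np.asarray(self.rf, dtype=complex))
        self.grad = np.atleast_2d(np.asarray(self.grad, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.rf.shape[0] < 1 or self.rf.shape[1] < 2:
            raise ValueError(f"rf must be (Nc>=1, Nt>=2), got {self.rf.shape}")
        if self.grad.shape != (3, self.rf.shape[1]):
            raise ValueError(
                f"grad must be (3, {self.rf.shape[1]}), got {self.grad.shape}"
            )
        if not (np.all(np.isfinite(self.rf)) and np.all(np.isfinite(self.grad))):
            raise ValueError("waveform samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.rf.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rf.shape[1]

    @property
    def duration(self) -> float:
        """Total pulse duration T = Nt * dt (s)."""
        return self.n_samples * self.dt

    @property
    def times(self) -> np.ndarray:
        """Midpoint sample times (s)."""
        return (np.arange(self.n_samples) + 0.5) * self.dt

    def copy(self) -> "PulseWaveforms":
        return PulseWaveforms(self.rf.copy(), self.grad.copy(), self.dt)

    def is_time_symmetric(self, atol: float = 1e-12) -> bool:
        """Element-wise time-mirror symmetry of RF and gradients."""
        return bool(
            np.allclose(self.rf, self.rf[:, ::-1], atol=atol)
            and np.allclose(self.grad, self.grad[:, ::-1], atol=atol)
        )


@dataclass
class HardwareLimits:
    """Scanner hardware/SAR constraints for the pulse design.

    Defaults are the limits of an 8-channel 7T head system: 70 mT/m gradient
    amplitude, 200 T/m/s slew rate, 190 V peak voltage, 8 W total and 1 W
    per-channel time-average RF power.
    """

    g_max: float = 70.0  # mT/m
    slew_max: float = 200.0  # T/m/s
    v_peak: float = 190.0  # V
    p_total: float = 8.0  # W
    p_channel: float = 1.0  # W

    def __post_init__(self) -> None:
        for name in ("g_max", "slew_max", "v_peak", "p_total", "p_channel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class LimitReport:
    """Measured extrema of a pulse against each hardware limit."""

    entries: dict = field(default_factory=dict)  # name -> (measured, limit, ok)

    @property
    def passed(self) -> bool:
        return all(ok for _, _, ok in self.entries.values())

    def measured(self, name: str) -> float:
        return self.entries[name][0]

    def __str__(self) -> str:
        lines = ["limit check:"]
        for name, (meas, lim, ok) in self.entries.items():
            lines.append(
                f"  {name:<12s} {meas:12.4f} / {lim:10.4f}  "
                f"{'ok' if ok else 'VIOLATED'}"
            )
        return "\n".join(lines)


def _sinc_envelope(n_samples: int, duration: float, tbw: float,
                   bw_scale: float) -> np.ndarray:
    """Hann-apodized sinc on the midpoint time grid, unit peak."""
    t = (np.arange(n_samples) + 0.5) / n_samples * duration - duration / 2
    bw = bw_scale * tbw / duration
    return np.sinc(bw * t) * np.cos(np.pi * t / duration) ** 2


def _envelope_fwhm(env: np.ndarray, dt: float) -> float:
    """FWHM (Hz) of the spectral magnitude of a sampled envelope."""
    n_pad = max(1 << 14, 8 * env.size)
    spec = np.abs(np.fft.rfft(env, n_pad))
    freqs = np.fft.rfftfreq(n_pad, dt)
    half = spec[0] / 2.0
    below = np.nonzero(spec < half)[0]
    if below.size == 0:
        raise ValueError("spectrum never drops below half maximum")
    i = below[0]
    # linear interpolation between the straddling bins
    f_half = freqs[i - 1] + (half - spec[i - 1]) / (spec[i] - spec[i - 1]) * (
        freqs[i] - freqs[i - 1]
    )
    return 2.0 * f_half


def make_cp_sinc(
    fa_deg: float,
    duration: float,
    tbw: float,
    n_channels: int = 8,
    dt: float = 10e-6,
    cp_phase_increment: float = 0.0,
    ref_sens_hz_per_v: float = REF_SENS_HZ_PER_V,
    sel_grad_mt_m: float = 0.0,
    sel_axis: int = 2,
) -> PulseWaveforms:
    """Build a CP-mode Hann-apodized sinc pulse.

    The envelope bandwidth is numerically calibrated so that the small-tip
    spectral FWHM equals ``tbw / duration`` (apodization alone would widen it
    by ~1-2%). The amplitude is scaled so the on-resonance small-tip flip
    angle at a reference voxel of combined sensitivity ``ref_sens_hz_per_v``
    equals ``fa_deg``. All channels carry the same waveform up to the phase
    increment ``exp(i * c * cp_phase_increment)``; the synthetic field maps
    are defined in the CP-aligned frame, so the default increment is zero.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if fa_deg < 0:
        raise ValueError(f"fa_deg must be non-negative, got {fa_deg}")
    if tbw < 2:
        raise ValueError(f"tbw must be >= 2, got {tbw}")

    n_samples = max(2, int(round(duration / dt)))

    # calibrate the sinc bandwidth so the spectral FWHM is exactly tbw/T
    target = tbw / duration
    lo, hi = 0.6, 1.4
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        fwhm = _envelope_fwhm(_sinc_envelope(n_samples, duration, tbw, mid), dt)
        if fwhm < target:
            lo = mid
        else:
            hi = mid
    env = _sinc_envelope(n_samples, duration, tbw, 0.5 * (lo + hi))

    # FA (cycles) = ref_sens * integral V dt  =>  peak voltage
    area = env.sum() * dt
    amp = (fa_deg / 360.0) / (ref_sens_hz_per_v * area)
    phases = np.exp(1j * cp_phase_increment * np.arange(n_channels))
    rf = amp * phases[:, None] * env[None, :]

    grad = np.zeros((3, n_samples))
    if sel_grad_mt_m != 0.0:
        grad[sel_axis, :] = sel_grad_mt_m
    return PulseWaveforms(rf, grad, dt)


def interpolation_matrix(n_old: int, dt_old: float, dt_new: float) -> np.ndarray:
    """Linear-resampling operator W: y_new = y_old @ W.T.

    Midpoint grids; piecewise-linear between the old midpoints with linear
    extrapolation beyond the outermost ones, so affine-in-time waveforms are
    reproduced exactly. Shape (n_new, n_old).
    """
    if dt_new <= 0:
        raise ValueError(f"dt_new must be positive, got {dt_new}")
    duration = n_old * dt_old
    n_new = max(2, int(round(duration / dt_new)))
    t_old = (np.arange(n_old) + 0.5) * dt_old
    t_new = (np.arange(n_new) + 0.5) * dt_new
    # segment index: t in [t_old[j], t_old[j+1]); edges reuse the end segments
    j = np.clip(np.searchsorted(t_old, t_new) - 1, 0, n_old - 2)
    u = (t_new - t_old[j]) / dt_old  # may fall outside [0,1] at the edges
    w = np.zeros((n_new, n_old))
    w[np.arange(n_new), j] = 1.0 - u
    w[np.arange(n_new), j + 1] = u
    return w


def resample_linear(pulse: PulseWaveforms, dt_new: float) -> PulseWaveforms:
    """Resample RF (re/im independently) and gradients onto a new grid.

    Piecewise-linear interpolation between midpoint sample times, with linear
    extrapolation at the edges so affine-in-time waveforms are reproduced
    exactly. Duration is preserved to within one new sample.
    """
    if dt_new <= 0:
        raise ValueError(f"dt_new must be positive, got {dt_new}")
    if dt_new == pulse.dt:
        return pulse.copy()
    w = interpolation_matrix(pulse.n_samples, pulse.dt, dt_new)
    return PulseWaveforms(pulse.rf @ w.T, pulse.grad @ w.T, dt_new)


def pulse_energy(pulse: PulseWaveforms,
                 impedance_ohm: float = DEFAULT_IMPEDANCE_OHM) -> float:
    """Deposited RF energy in mJ: sum_c sum_n |V|^2 dt / R."""
    if impedance_ohm <= 0:
        raise ValueError("impedance must be positive")
    e_joule = np.sum(np.abs(pulse.rf) ** 2) * pulse.dt / impedance_ohm
    return float(e_joule * 1e3)


def _slew_rates(pulse: PulseWaveforms) -> np.ndarray:
    """Per-axis slew including the ramps from/to zero at the pulse edges.

    Gradients are in mT/m, dt in s; returned slew is in T/m/s.
    """
    padded = np.pad(pulse.grad, ((0, 0), (1, 1)))
    return np.diff(padded, axis=1) * 1e-3 / pulse.dt


def check_limits(
    pulse: PulseWaveforms,
    limits: HardwareLimits,
    impedance_ohm: float = DEFAULT_IMPEDANCE_OHM,
    rtol: float = 1e-9,
) -> LimitReport:
    """Measure pulse extrema against hardware limits (report, not exception).

    Power entries are time-averages over the pulse duration at the given
    impedance.
    """
    p_per_channel = (
        np.sum(np.abs(pulse.rf) ** 2, axis=1) * pulse.dt
        / impedance_ohm / pulse.duration
    )
    measured = {
        "v_peak": (float(np.max(np.abs(pulse.rf))), limits.v_peak),
        "g_max": (float(np.max(np.abs(pulse.grad))), limits.g_max),
        "slew_max": (float(np.max(np.abs(_slew_rates(pulse)))), limits.slew_max),
        "p_channel": (float(np.max(p_per_channel)), limits.p_channel),
        "p_total": (float(np.sum(p_per_channel)), limits.p_total),
    }
    report = LimitReport()
    for name, (meas, lim) in measured.items():
        report.entries[name] = (meas, lim, meas <= lim * (1 + rtol))
    return report


def half_length(n_samples: int) -> int:
    """Number of free samples in a time-symmetric pulse of length n_samples."""
    return (n_samples + 1) // 2


def symmetrize(rf_half: np.ndarray, grad_half: np.ndarray, dt: float,
               n_samples: int, hermitian: bool = False) -> PulseWaveforms:
    """Mirror first-half waveforms into a full time-symmetric pulse.

    ``rf_half`` is (Nc, Nh) complex and ``grad_half`` (3, Nh) with
    Nh = ceil(n_samples / 2); the center sample is shared when n_samples is
    odd. Gradients always mirror element-wise. By default the RF mirrors
    element-wise too, rf[:, n] == rf[:, Nt-1-n]; this admits static
    per-channel phase shims (complex weights on a shared real envelope),
    for which the small-tip spectral phase is linear with slope -pi*T up to
    a per-voxel intercept, but does not by itself guarantee linear phase
    for arbitrary complex waveforms — the design cost's phase-consistency
    term enforces that. ``hermitian=True`` instead mirrors conjugately,
    rf[:, n] == conj(rf[:, Nt-1-n]): a Hermitian-symmetric waveform has a
    real spectrum, so linear spectral phase is guaranteed by construction
    (at the price of a spatially uniform phase intercept, which excludes
    phase shimming). With an odd sample count the center sample's imaginary
    part is dropped in Hermitian mode (the symmetry forces it real).
    """
    rf_half = np.atleast_2d(np.asarray(rf_half, dtype=complex))
    grad_half = np.atleast_2d(np.asarray(grad_half, dtype=float))
    nh = half_length(n_samples)
    if rf_half.shape[1] != nh or grad_half.shape != (3, nh):
        raise ValueError(
            f"half waveforms must have {nh} samples for Nt={n_samples}; "
            f"got rf {rf_half.shape}, grad {grad_half.shape}"
        )
    tail = n_samples - nh  # samples mirrored from the half
    if hermitian:
        rf_half = rf_half.copy()
        if n_samples % 2:
            rf_half[:, -1] = rf_half[:, -1].real
        rf_tail = rf_half[:, :tail][:, ::-1].conj()
    else:
        rf_tail = rf_half[:, :tail][:, ::-1]
    rf = np.concatenate([rf_half, rf_tail], axis=1)
    grad = np.concatenate([grad_half, grad_half[:, :tail][:, ::-1]], axis=1)
    return PulseWaveforms(rf, grad, dt)


def extract_half(pulse: PulseWaveforms) -> tuple[np.ndarray, np.ndarray]:
    """First-half (plus center if odd) RF and gradient samples."""
    nh = half_length(pulse.n_samples)
    return pulse.rf[:, :nh].copy(), pulse.grad[:, :nh].copy()


def write_pulse(path, pulse: PulseWaveforms, meta: dict | None = None) -> None:
    """Serialize a pulse to a structured JSON text archive (lossless doubles)."""
    payload = {
        "rf_real": pulse.rf.real.tolist(),
        "rf_imag": pulse.rf.imag.tolist(),
        "grad": pulse.grad.tolist(),
        "dt_s": pulse.dt,
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_pulse(path) -> tuple[PulseWaveforms, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    rf = np.asarray(payload["rf_real"]) + 1j * np.asarray(payload["rf_imag"])
    pulse = PulseWaveforms(rf, np.asarray(payload["grad"]), payload["dt_s"])
    return pulse, payload.get("meta", {})
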