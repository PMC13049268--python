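"""Extended phase graph (EPG) simulation of a vFA TSE echo train.

Maps per-voxel excitation quality (flip angle and phase) to the signal of a
variable-flip-angle turbo spin echo: the excitation populates the F states
from Z, and every refocusing period applies relaxation over the two half
spacings, a unit gradient-dephasing shift per half spacing, and the RF
mixing matrix of the refocusing flip/phase; the echo amplitude is read from
the F0 state midway between pulses. With the CPMG condition (excitation
phase 90 deg off the refocusing phase) an ideal 90/180 train refocuses every
echo to unit amplitude in the absence of relaxation.

State convention (configuration orders k >= 0): ``fp[k] = F(+k)``,
``fm[k] = conj(F(-k))``, ``z[k]``; RF rotations are instantaneous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPGConfig",
    "EchoTrain",
    "epg_simulate",
    "signal_map",
    "default_vfa_train",
    "write_train",
    "read_train",
]


@dataclass
class EPGConfig:
    """Refocusing train and tissue parameters for the EPG simulation.

    ``spacings_ms[i]`` is the echo spacing of period ``i`` (previous echo or
    excitation to echo ``i``); the refocusing pulse sits at its center. The
    default tissue values (T1 1500 ms, T2 60 ms) are plausible 7T brain
    white-matter numbers and are configurable, not a claim.
    """

    flips_deg: np.ndarray
    phases_rad: np.ndarray
    spacings_ms: np.ndarray
    t1_ms: float = 1500.0
    t2_ms: float = 60.0
    target_echo: int = 17

    def __post_init__(self) -> None:
        self.flips_deg = np.atleast_1d(np.asarray(self.flips_deg, dtype=float))
        self.phases_rad = np.atleast_1d(np.asarray(self.phases_rad, dtype=float))
        self.spacings_ms = np.atleast_1d(np.asarray(self.spacings_ms, dtype=float))
        n = self.flips_deg.size
        if self.phases_rad.size != n or self.spacings_ms.size != n:
            raise ValueError("flips, phases and spacings must have equal length")
        if np.any(self.flips_deg < 0) or np.any(self.flips_deg > 180):
            raise ValueError("refocusing flips must lie in [0, 180] deg")
        if np.any(self.spacings_ms <= 0):
            raise ValueError("echo spacings must be positive")
        if not 0 <= self.target_echo < n:
            raise ValueError("target_echo outside the train")

    @property
    def n_echoes(self) -> int:
        return self.flips_deg.size


@dataclass
class EchoTrain:
    """Complex echo amplitudes in units of M0."""

    echoes: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))

    def __post_init__(self) -> None:
        self.echoes = np.atleast_1d(np.asarray(self.echoes, dtype=complex))


def _rf_matrix(alpha_rad: np.ndarray, phi_rad: np.ndarray) -> np.ndarray:
    """EPG RF mixing matrices, shape (..., 3, 3), acting on (fp, fm, z)."""
    a2 = alpha_rad / 2.0
    c2, s2 = np.cos(a2) ** 2, np.sin(a2) ** 2
    sa, ca = np.sin(alpha_rad), np.cos(alpha_rad)
    ep = np.exp(1j * phi_rad)
    t = np.empty(np.shape(alpha_rad) + (3, 3), dtype=complex)
    t[..., 0, 0] = c2
    t[..., 0, 1] = ep**2 * s2
    t[..., 0, 2] = -1j * ep * sa
    t[..., 1, 0] = ep.conj() ** 2 * s2
    t[..., 1, 1] = c2
    t[..., 1, 2] = 1j * ep.conj() * sa
    t[..., 2, 0] = -0.5j * ep.conj() * sa
    t[..., 2, 1] = 0.5j * ep * sa
    t[..., 2, 2] = ca
    return t


class _EPGStates:
    """Vectorized EPG state arrays for N independent voxels."""

    def __init__(self, n_voxels: int, n_orders: int):
        self.fp = np.zeros((n_voxels, n_orders), dtype=complex)
        self.fm = np.zeros((n_voxels, n_orders), dtype=complex)
        self.z = np.zeros((n_voxels, n_orders), dtype=complex)
        self.z[:, 0] = 1.0

    def excite(self, fa_rad: np.ndarray, phase_rad: np.ndarray) -> None:
        t = _rf_matrix(fa_rad, phase_rad)
        self.rf_from_matrix(t)

    def rf_from_matrix(self, t: np.ndarray) -> None:
        fp = (
            t[..., 0, 0, None] * self.fp
            + t[..., 0, 1, None] * self.fm
            + t[..., 0, 2, None] * self.z
        )
        fm = (
            t[..., 1, 0, None] * self.fp
            + t[..., 1, 1, None] * self.fm
            + t[..., 1, 2, None] * self.z
        )
        z = (
            t[..., 2, 0, None] * self.fp
            + t[..., 2, 1, None] * self.fm
            + t[..., 2, 2, None] * self.z
        )
        self.fp, self.fm, self.z = fp, fm, z

    def relax(self, tau_ms: float, t1_ms: float, t2_ms: float) -> None:
        e1 = np.exp(-tau_ms / t1_ms) if np.isfinite(t1_ms) else 1.0
        e2 = np.exp(-tau_ms / t2_ms) if np.isfinite(t2_ms) else 1.0
        self.fp *= e2
        self.fm *= e2
        self.z *= e1
        self.z[:, 0] += 1.0 - e1

    def shift(self) -> None:
        """Unit positive gradient dephasing: F(k) -> F(k+1)."""
        self.fp[:, 1:] = self.fp[:, :-1]
        self.fp[:, 0] = self.fm[:, 1].conj()
        self.fm[:, :-1] = self.fm[:, 1:]
        self.fm[:, -1] = 0.0


def _simulate(fa_deg: np.ndarray, phase_rad: np.ndarray,
              cfg: EPGConfig) -> np.ndarray:
    """Echo amplitudes (N voxels x n_echoes)."""
    fa_deg = np.atleast_1d(np.asarray(fa_deg, dtype=float))
    phase_rad = np.atleast_1d(np.asarray(phase_rad, dtype=float))
    n = fa_deg.size
    states = _EPGStates(n, cfg.n_echoes + 2)
    states.excite(np.radians(fa_deg), phase_rad)
    echoes = np.empty((n, cfg.n_echoes), dtype=complex)
    refoc = _rf_matrix(np.radians(cfg.flips_deg), cfg.phases_rad)
    for i in range(cfg.n_echoes):
        half = cfg.spacings_ms[i] / 2.0
        states.relax(half, cfg.t1_ms, cfg.t2_ms)
        states.shift()
        states.rf_from_matrix(np.broadcast_to(refoc[i], (n, 3, 3)))
        states.relax(half, cfg.t1_ms, cfg.t2_ms)
        states.shift()
        echoes[:, i] = states.fp[:, 0]
    return echoes


def epg_simulate(exc_fa_deg: float, exc_phase_rad: float,
                 cfg: EPGConfig) -> EchoTrain:
    """Echo train for a single voxel's excitation flip angle and phase."""
    return EchoTrain(_simulate(exc_fa_deg, exc_phase_rad, cfg)[0])


def signal_map(exc_fa_map: np.ndarray, exc_phase_map: np.ndarray,
               cfg: EPGConfig) -> np.ndarray:
    """Per-voxel magnitude of the target ("central") echo.

    ``exc_fa_map`` (deg) and ``exc_phase_map`` (rad) may have any common
    shape; the result has the same shape.
    """
    fa = np.asarray(exc_fa_map, dtype=float)
    ph = np.asarray(exc_phase_map, dtype=float)
    if fa.shape != ph.shape:
        raise ValueError(
            f"flip-angle map {fa.shape} and phase map {ph.shape} disagree"
        )
    echoes = _simulate(fa.ravel(), ph.ravel(), cfg)
    return np.abs(echoes[:, cfg.target_echo]).reshape(fa.shape)


def default_vfa_train(
    n_echoes: int = 107,
    echo_spacing_ms: float = 6.65,
    first_spacing_ms: float = 12.5,
    start_deg: float = 120.0,
    min_deg: float = 55.0,
    end_deg: float = 110.0,
    target_echo: int = 17,
    t1_ms: float = 1500.0,
    t2_ms: float = 60.0,
) -> EPGConfig:
    """A generic variable-flip-angle refocusing train.

    Descends from ``start_deg`` to a sustained ``min_deg`` plateau and ramps
    back up toward ``end_deg`` at the train end — the usual vFA shape that
    trades echo amplitude for a flat signal response over the train. All
    refocusing phases are zero; pair with an excitation phase of +pi/2 for
    CPMG. The first echo spacing is set by the excitation pulse length and
    is the knob the central-echo signal is most sensitive to.
    """
    n_down = max(2, n_echoes // 5)
    n_up = max(2, n_echoes // 4)
    n_hold = n_echoes - n_down - n_up
    flips = np.concatenate(
        [
            np.linspace(start_deg, min_deg, n_down),
            np.full(n_hold, min_deg),
            np.linspace(min_deg, end_deg, n_up),
        ]
    )
    spacings = np.full(n_echoes, echo_spacing_ms)
    spacings[0] = first_spacing_ms
    return EPGConfig(
        flips_deg=flips,
        phases_rad=np.zeros(n_echoes),
        spacings_ms=spacings,
        t1_ms=t1_ms,
        t2_ms=t2_ms,
        target_echo=min(target_echo, n_echoes - 1),
    )


def write_train(path, cfg: EPGConfig) -> None:
    """Plain-text train file: '# t1_ms t2_ms target_echo' header, then one
    'flip_deg phase_rad spacing_ms' row per refocusing pulse."""
    with open(path, "w") as fh:
        fh.write(f"# t1_ms={cfg.t1_ms} t2_ms={cfg.t2_ms} "
                 f"target_echo={cfg.target_echo}\n")
        for f, p, s in zip(cfg.flips_deg, cfg.phases_rad, cfg.spacings_ms):
            fh.write(f"{f:.17g} {p:.17g} {s:.17g}\n")


def read_train(path) -> EPGConfig:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    meta[k] = float(v)
                continue
            rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows)
    return EPGConfig(
        flips_deg=arr[:, 0],
        phases_rad=arr[:, 1],
        spacings_ms=arr[:, 2],
        t1_ms=meta.get("t1_ms", 1500.0),
        t2_ms=meta.get("t2_ms", 60.0),
        target_echo=int(meta.get("target_echo", 0)),
    )
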