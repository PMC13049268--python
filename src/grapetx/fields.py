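"""Synthetic multi-subject B1+/dB0 head models and NIfTI serialization.

The generator emulates the field maps an 8-channel transmit head array
produces at 7T: an ellipsoidal head, loop-like channel sensitivities whose
magnitude decays with distance from each coil element and whose phase
advances with RF propagation depth (so the CP combination interferes
constructively at the head center, reproducing the characteristic
center-bright / periphery-dark CP mode), and a dB0 map composed of a smooth
low-order spatial polynomial plus localized off-resonance hotspots near the
air-filled cavities (frontal sinuses, ear canals). Maps are expressed in the
CP-aligned frame: the azimuthal phase rotation of the physical array is
absorbed into the channel definition, as CP-calibrated relative maps are in
practice, so equal channel drive is the CP mode.

Every subject is a pure function of (CohortConfig, subject_index): head
size, position, tilt, coil loading and hotspot strengths are jittered with
a deterministic per-subject stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .constants import REF_SENS_HZ_PER_V

__all__ = [
    "SubjectFieldMap",
    "CohortConfig",
    "generate_subject",
    "generate_cohort",
    "write_fieldmap",
    "read_fieldmap",
    "write_cohort",
    "read_cohort",
]

N_CHANNELS = 8


@dataclass
class SubjectFieldMap:
    """Per-voxel transmit sensitivities, off-resonance and brain mask.

    ``sens`` is (Nc, nx, ny, nz) complex in Hz/V, ``db0`` (nx, ny, nz) in Hz,
    ``mask`` boolean. Voxel centers sit on a uniform grid with the given
    spacing (mm) and origin (mm, scanner frame, isocenter at 0).
    """

    sens: np.ndarray
    db0: np.ndarray
    mask: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray
    subject_id: str

    def __post_init__(self) -> None:
        self.sens = np.asarray(self.sens, dtype=complex)
        self.db0 = np.asarray(self.db0, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.sens.ndim != 4:
            raise ValueError("sens must be (Nc, nx, ny, nz)")
        if self.db0.shape != self.sens.shape[1:] or self.mask.shape != self.db0.shape:
            raise ValueError("sens/db0/mask grid shapes disagree")
        if not np.all(np.isfinite(self.sens)):
            raise ValueError("sensitivities must be finite")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple:
        return self.db0.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def pos(self) -> np.ndarray:
        """Voxel center coordinates, (nx, ny, nz, 3) in mm."""
        grids = np.meshgrid(
            *[self.origin_mm[a] + self.spacing_mm * np.arange(self.shape[a])
              for a in range(3)],
            indexing="ij",
        )
        return np.stack(grids, axis=-1)

    def masked_sens(self) -> np.ndarray:
        """(Nvox, Nc) sensitivity rows over the mask."""
        return self.sens[:, self.mask].T

    def masked_db0(self) -> np.ndarray:
        return self.db0[self.mask]

    def masked_pos(self) -> np.ndarray:
        return self.pos[self.mask]

    def cp_mode(self) -> np.ndarray:
        """Combined CP-mode sensitivity sum_c s_c on the grid."""
        return self.sens.sum(axis=0)


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort generator (defaults: 20 subjects).

    The default grid (24 x 20 x 20 at 5 mm) yields roughly 3-4k brain voxels
    per subject, a desk-scale stand-in for acquired 4-5 mm field maps.
    """

    n_subjects: int = 20
    shape: tuple = (24, 20, 20)
    spacing_mm: float = 5.0
    head_semiaxes_mm: tuple = (55.0, 42.0, 42.0)
    coil_radius_mm: float = 80.0
    coil_decay_mm: float = 65.0
    prop_phase_rad_per_mm: float = 0.048
    db0_smooth_hz: float = 150.0
    db0_hotspot_hz: float = 600.0
    hotspot_sigma_mm: float = 14.0
    jitter_size: float = 0.05
    jitter_shift_mm: float = 4.0
    jitter_tilt_deg: float = 5.0
    jitter_loading: float = 0.10
    master_seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if min(self.shape) < 2:
            raise ValueError(f"degenerate grid shape {self.shape}")


def _rotation_matrix(tilt_x_rad: float, tilt_y_rad: float) -> np.ndarray:
    cx, sx = np.cos(tilt_x_rad), np.sin(tilt_x_rad)
    cy, sy = np.cos(tilt_y_rad), np.sin(tilt_y_rad)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return ry @ rx


def generate_subject(config: CohortConfig, subject_index: int) -> SubjectFieldMap:
    """Generate one pseudo-subject's field maps, deterministically.

    The CP combination is normalized so its mean magnitude over the brain
    mask equals the package reference sensitivity (47 Hz/V), which makes the
    reference-calibrated CP sinc hit its nominal flip angle on average.
    """
    rng = np.random.default_rng([config.master_seed, subject_index])
    shape = config.shape
    origin = -(np.asarray(shape) - 1) / 2.0 * config.spacing_mm

    grids = np.meshgrid(
        *[origin[a] + config.spacing_mm * np.arange(shape[a]) for a in range(3)],
        indexing="ij",
    )
    pos = np.stack(grids, axis=-1)  # (nx,ny,nz,3) mm

    # per-subject head geometry jitter
    semi = np.asarray(config.head_semiaxes_mm) * (
        1 + config.jitter_size * rng.uniform(-1, 1, 3)
    )
    shift = config.jitter_shift_mm * rng.uniform(-1, 1, 3)
    tilt = np.radians(config.jitter_tilt_deg) * rng.uniform(-1, 1, 2)
    rot = _rotation_matrix(*tilt)
    # head-frame coordinates
    hpos = (pos - shift) @ rot
    radial2 = ((hpos / semi) ** 2).sum(axis=-1)
    mask = radial2 <= 1.0
    if not mask.any():
        raise ValueError("degenerate grid: ellipsoid mask is empty")

    # channel sensitivities from loop-like sources on a ring (head frame)
    angles = 2 * np.pi * np.arange(N_CHANNELS) / N_CHANNELS
    sens = np.empty((N_CHANNELS,) + shape, dtype=complex)
    loading_mag = 1 + config.jitter_loading * rng.uniform(-1, 1, N_CHANNELS)
    loading_ph = 0.3 * rng.uniform(-1, 1, N_CHANNELS)
    for c in range(N_CHANNELS):
        src = config.coil_radius_mm * np.array(
            [np.cos(angles[c]), np.sin(angles[c]), 0.0]
        )
        d = np.linalg.norm(hpos - src, axis=-1)
        mag = loading_mag[c] / (1.0 + (d / config.coil_decay_mm) ** 2)
        phase = -config.prop_phase_rad_per_mm * d + loading_ph[c]
        sens[c] = mag * np.exp(1j * phase)

    cp = np.abs(sens.sum(axis=0))
    sens *= REF_SENS_HZ_PER_V / cp[mask].mean()

    # smooth low-order dB0 polynomial, normalized to the configured amplitude
    u = hpos / semi  # normalized head coordinates
    coeffs = rng.uniform(-1, 1, 9)
    smooth = (
        coeffs[0]
        + coeffs[1] * u[..., 0] + coeffs[2] * u[..., 1] + coeffs[3] * u[..., 2]
        + coeffs[4] * u[..., 0] * u[..., 1] + coeffs[5] * u[..., 1] * u[..., 2]
        + coeffs[6] * u[..., 0] ** 2 + coeffs[7] * u[..., 1] ** 2
        + coeffs[8] * u[..., 2] ** 2
    )
    peak = np.abs(smooth[mask]).max()
    if peak > 0:
        smooth = smooth * (config.db0_smooth_hz / peak)

    # hotspots near the anterior-inferior (sinuses) and lateral-inferior
    # (ear canals) mask boundary, in the head frame
    centers = np.array(
        [
            [0.0, 0.85 * semi[1], -0.55 * semi[2]],
            [0.85 * semi[0], 0.0, -0.55 * semi[2]],
            [-0.85 * semi[0], 0.0, -0.55 * semi[2]],
        ]
    )
    hotspot = np.zeros(shape)
    signs = np.array([1.0, -1.0, -1.0])
    strengths = config.db0_hotspot_hz * rng.uniform(0.5, 1.0, len(centers))
    for center, sign, strength in zip(centers, signs, strengths):
        d2 = ((hpos - center) ** 2).sum(axis=-1)
        hotspot += sign * strength * np.exp(-d2 / (2 * config.hotspot_sigma_mm**2))
    # guarantee |db0| <= smooth amplitude + hotspot amplitude
    hotspot = np.clip(hotspot, -config.db0_hotspot_hz, config.db0_hotspot_hz)
    db0 = (smooth + hotspot) * mask

    return SubjectFieldMap(
        sens=sens * mask,
        db0=db0,
        mask=mask,
        spacing_mm=config.spacing_mm,
        origin_mm=origin,
        subject_id=f"sub-{subject_index:03d}",
    )


def generate_cohort(config: CohortConfig) -> list[SubjectFieldMap]:
    """Generate the full pseudo-subject database (default 20 subjects)."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]


def _affine(subject: SubjectFieldMap) -> np.ndarray:
    aff = np.diag([subject.spacing_mm] * 3 + [1.0])
    aff[:3, 3] = subject.origin_mm
    return aff


def write_fieldmap(subject: SubjectFieldMap, out_dir) -> Path:
    """Write one subject as a set of NIfTI volumes; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(subject)
    sid = subject.subject_id
    for c in range(subject.sens.shape[0]):
        for part, arr in (("real", subject.sens[c].real),
                          ("imag", subject.sens[c].imag)):
            nib.save(nib.Nifti1Image(arr.astype(np.float64), aff),
                     out / f"{sid}_sens{c:02d}_{part}.nii")
    nib.save(nib.Nifti1Image(subject.db0.astype(np.float64), aff),
             out / f"{sid}_db0.nii")
    nib.save(nib.Nifti1Image(subject.mask.astype(np.uint8), aff),
             out / f"{sid}_mask.nii")
    return out


def read_fieldmap(in_dir, subject_id: str, n_channels: int = N_CHANNELS
                  ) -> SubjectFieldMap:
    """Read a subject written by :func:`write_fieldmap`.

    Raises with the offending file named on missing volumes or shape
    mismatches.
    """
    in_dir = Path(in_dir)

    def load(name: str) -> tuple[np.ndarray, np.ndarray]:
        path = in_dir / name
        if not path.exists():
            raise FileNotFoundError(f"missing field-map volume: {path}")
        img = nib.load(path)
        return np.asarray(img.dataobj, dtype=float), img.affine

    db0, aff = load(f"{subject_id}_db0.nii")
    mask, _ = load(f"{subject_id}_mask.nii")
    if mask.shape != db0.shape:
        raise ValueError(
            f"shape mismatch in {subject_id}_mask.nii: {mask.shape} vs {db0.shape}"
        )
    sens = np.empty((n_channels,) + db0.shape, dtype=complex)
    for c in range(n_channels):
        re, _ = load(f"{subject_id}_sens{c:02d}_real.nii")
        im, _ = load(f"{subject_id}_sens{c:02d}_imag.nii")
        for part, arr in (("real", re), ("imag", im)):
            if arr.shape != db0.shape:
                raise ValueError(
                    f"shape mismatch in {subject_id}_sens{c:02d}_{part}.nii: "
                    f"{arr.shape} vs {db0.shape}"
                )
        sens[c] = re + 1j * im
    spacing = float(aff[0, 0])
    origin = aff[:3, 3].copy()
    return SubjectFieldMap(sens, db0, mask > 0.5, spacing, origin, subject_id)


def write_cohort(cohort: list[SubjectFieldMap], out_dir,
                 config: CohortConfig | None = None) -> Path:
    """Write all subjects plus a manifest file; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = []
    for s in cohort:
        write_fieldmap(s, out)
        subjects.append({"subject_id": s.subject_id,
                         "n_channels": int(s.sens.shape[0])})
    manifest = {
        "subjects": subjects,
        "config": asdict(config) if config is not None else None,
    }
    path = out / "cohort_manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_cohort(manifest_path) -> list[SubjectFieldMap]:
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    return [
        read_fieldmap(manifest_path.parent, entry["subject_id"],
                      entry["n_channels"])
        for entry in manifest["subjects"]
    ]
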