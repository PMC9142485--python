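"""Analytic single-sphere dipole forward model and 10-mm lead field.

A current dipole inside a homogeneous conducting sphere with an insulating
exterior has a closed-form surface potential.  Writing ``f = b/R`` for the
relative dipole eccentricity, ``x = cos γ`` for the angle between dipole and
electrode position vectors (seen from the sphere center) and
``g = sqrt(1 − 2 f x + f²)``, the Legendre series

    V = 1/(4π σ R²) Σ_n (2n+1)/n · f^(n−1) · [ n q_r P_n(x) + q_t P_n¹(x) ]

sums to

    V = 1/(4π σ R²) · [ q_r S₁ + (q·ê_t) s T ]
    S₁ = 2 (x − f)/g³ + (1/f)(1/g − 1)
    T  = 2/g³ + (1 + g) / (g (1 − f x + g))

with ``s = sin γ`` and ``ê_t`` the tangential unit vector toward the
electrode.  The series itself serves as an independent oracle in the tests.

Units: positions mm, dipole moments nAm, potentials µV, conductivity S/m.
All returned potentials are average-referenced (common reference removed),
matching the recording reference of the analysis chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .montage import Montage, default_montage

logger = logging.getLogger(__name__)

#: Brain conductivity used throughout (S/m).
CONDUCTIVITY_S_PER_M = 0.33


def _sphere_potential_unreferenced(
    position_mm: np.ndarray,
    moment_nam: np.ndarray,
    elec_mm: np.ndarray,
    center_mm: np.ndarray,
    radius_mm: float,
    sigma: float = CONDUCTIVITY_S_PER_M,
) -> np.ndarray:
    """Surface potential (µV) of one dipole at every electrode, no re-referencing."""
    r0 = (np.asarray(position_mm, float) - center_mm) / 1000.0  # m
    q = np.asarray(moment_nam, float) * 1e-9  # A·m
    re = (np.asarray(elec_mm, float) - center_mm) / 1000.0  # (n_e, 3) m
    R = radius_mm / 1000.0
    b = np.linalg.norm(r0)
    re_hat = re / np.linalg.norm(re, axis=1, keepdims=True)
    if b < 1e-12:
        # dipole at the center: only the n=1 term survives
        v = 3.0 * (re_hat @ q) / (4.0 * np.pi * sigma * R**2)
        return v * 1e6
    f = b / R
    r0_hat = r0 / b
    x = np.clip(re_hat @ r0_hat, -1.0, 1.0)
    g = np.sqrt(1.0 - 2.0 * f * x + f * f)
    q_r = q @ r0_hat
    # q·(ê_t) sinγ  ==  q·r̂_e − x q_r   (tangential projection, no 1/sinγ)
    qt_s = re_hat @ q - x * q_r
    s1 = 2.0 * (x - f) / g**3 + (1.0 / g - 1.0) / f
    t = 2.0 / g**3 + (1.0 + g) / (g * (1.0 - f * x + g))
    v = (q_r * s1 + qt_s * t) / (4.0 * np.pi * sigma * R**2)
    return v * 1e6


def dipole_potential(
    position_mm: np.ndarray,
    moment_nam: np.ndarray,
    montage: Montage,
    sigma: float = CONDUCTIVITY_S_PER_M,
) -> np.ndarray:
    """Average-referenced scalp potential (µV per electrode) of one dipole.

    Parameters
    ----------
    position_mm : (3,) dipole location, MNI mm; must lie strictly inside the
        model sphere.
    moment_nam : (3,) dipole moment in nAm.
    montage : electrode montage whose positions lie on the model sphere.
    """
    position_mm = np.asarray(position_mm, float)
    ecc = np.linalg.norm(position_mm - montage.sphere_center)
    if ecc >= montage.sphere_radius:
        raise ValueError(
            f"dipole at eccentricity {ecc:.1f} mm is not strictly inside the "
            f"{montage.sphere_radius:.0f} mm sphere"
        )
    v = _sphere_potential_unreferenced(
        position_mm, moment_nam, montage.positions, montage.sphere_center, montage.sphere_radius, sigma
    )
    return v - v.mean()


@dataclass
class SourceGrid:
    """10-mm isotropic source grid in MNI mm with a brain mask."""

    voxels_mm: np.ndarray  # (n_voxels, 3), retained (in-mask) voxel centers
    spacing_mm: float = 10.0

    @property
    def n_voxels(self) -> int:
        return len(self.voxels_mm)

    def nearest(self, point_mm: np.ndarray) -> int:
        return int(np.argmin(np.linalg.norm(self.voxels_mm - np.asarray(point_mm, float), axis=1)))

    def volume_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ijk indices, volume shape, origin) for packing voxel vectors into a 3-D array."""
        origin = self.voxels_mm.min(axis=0)
        ijk = np.round((self.voxels_mm - origin) / self.spacing_mm).astype(int)
        shape = ijk.max(axis=0) + 1
        return ijk, shape, origin

    def to_volume(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        ijk, shape, _ = self.volume_index()
        vol = np.full(tuple(shape), fill, dtype=float)
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = values
        return vol

    def affine(self) -> np.ndarray:
        _, _, origin = self.volume_index()
        aff = np.diag([self.spacing_mm] * 3 + [1.0])
        aff[:3, 3] = origin
        return aff

    def to_nifti(self, values: np.ndarray, path: str | Path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.to_volume(values, fill=0.0).astype(np.float32), self.affine())
        nib.save(img, str(path))


# MNI bounding box intersected with the shrunk sphere to form the brain mask
_MNI_BOX_MM = np.array([[-70.0, 70.0], [-100.0, 70.0], [-40.0, 75.0]])


def default_grid(spacing_mm: float = 10.0, montage: Montage | None = None) -> SourceGrid:
    """Brain-masked grid: sphere shrunk 10 % intersected with an MNI bounding box."""
    montage = montage or default_montage()
    r_in = 0.9 * montage.sphere_radius
    axes = [np.arange(lo, hi + 0.5 * spacing_mm, spacing_mm) for lo, hi in _MNI_BOX_MM]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.c_[xx.ravel(), yy.ravel(), zz.ravel()]
    inside = np.linalg.norm(pts - montage.sphere_center, axis=1) <= r_in
    return SourceGrid(pts[inside], spacing_mm=spacing_mm)


@dataclass
class LeadField:
    """Gain matrix mapping unit dipoles (per voxel and cartesian axis) to scalp µV."""

    grid: SourceGrid
    montage: Montage
    gain: np.ndarray  # (n_voxels, 3, n_channels), average-referenced

    def condition_summary(self) -> dict[str, float]:
        flat = self.gain.reshape(-1, self.gain.shape[-1])
        sv = np.linalg.svd(flat, compute_uv=False)
        rank = int((sv > sv[0] * 1e-10).sum())
        return {"rank": rank, "cond": float(sv[0] / sv[rank - 1]), "n_voxels": self.grid.n_voxels}

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("gain", data=self.gain, compression="gzip")
            fh.create_dataset("voxels_mm", data=self.grid.voxels_mm)
            fh.attrs["spacing_mm"] = self.grid.spacing_mm
            fh.attrs["labels"] = np.array(self.montage.labels, dtype="S")

    @classmethod
    def load(cls, path: str | Path, montage: Montage | None = None) -> "LeadField":
        montage = montage or default_montage()
        with h5py.File(path, "r") as fh:
            gain = fh["gain"][()]
            grid = SourceGrid(fh["voxels_mm"][()], spacing_mm=float(fh.attrs["spacing_mm"]))
            labels = [s.decode() for s in fh.attrs["labels"]]
        if labels != montage.labels:
            raise ValueError("cached lead field does not match the montage")
        return cls(grid, montage, gain)


def build_leadfield(grid: SourceGrid, montage: Montage | None = None) -> LeadField:
    """Three-orientation gain per retained voxel; voxels outside the sphere are dropped."""
    montage = montage or default_montage()
    ecc = np.linalg.norm(grid.voxels_mm - montage.sphere_center, axis=1)
    keep = ecc < montage.sphere_radius - 1e-9
    if not keep.all():
        logger.warning("excluding %d grid voxels outside the model sphere", (~keep).sum())
        grid = SourceGrid(grid.voxels_mm[keep], spacing_mm=grid.spacing_mm)
    n_v, n_c = grid.n_voxels, montage.n_channels
    gain = np.empty((n_v, 3, n_c))
    eye = np.eye(3)
    for i, vox in enumerate(grid.voxels_mm):
        for ax in range(3):
            gain[i, ax] = dipole_potential(vox, eye[ax], montage)
    return LeadField(grid, montage, gain)
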