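"""Scalar minimum-variance (LCMV) beamformer source power analysis.

Windowed band-limited channel covariances (Hanning-tapered sliding windows,
300 ms width, 50 ms hop, cross-spectra summed over the band's 1 Hz bins)
are projected to a 10-mm source grid through the spherical-head lead field.
At each voxel the scalar beamformer picks the dipole orientation maximizing
unit-gain output power (the smallest-eigenvalue direction of L' C⁻¹ L) and
common per-band weights are computed from the all-window covariance, then
applied to every window (a common spatial filter avoids window-to-window
weight instability).  Per-voxel log power is baseline-corrected to dB and
compared with sign-flip permutation statistics and spatial (face-adjacent)
cluster correction, SnPM style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .erp_stats import NDClusterResult, sign_flip_cluster_nd
from .forward import LeadField, SourceGrid

#: Analysis frequency bands (Hz, inclusive edges).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (21.0, 30.0),
    "gamma": (31.0, 45.0),
}


def window_csd(
    data: np.ndarray,
    sfreq: float,
    t0_index: int,
    center_ms: float,
    band_hz: tuple[float, float],
    win_ms: float = 300.0,
    fstep: float = 1.0,
) -> np.ndarray:
    """Trial-averaged cross-spectral (channel covariance) matrix for one window.

    Hanning-tapered DFT coefficients on the band's 1 Hz grid, averaged over
    trials and band bins.  Returns a Hermitian PSD complex matrix.
    """
    x = np.asarray(data)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need (n_trials >= 2, n_channels, n_times) data")
    n_win = int(round(win_ms / 1000.0 * sfreq))
    start = int(round(center_ms / 1000.0 * sfreq)) + t0_index - n_win // 2
    if start < 0 or start + n_win > x.shape[2]:
        raise ValueError(f"window at {center_ms} ms falls outside the epoch")
    seg = x[:, :, start : start + n_win]
    freqs = np.arange(band_hz[0], band_hz[1] + 0.5 * fstep, fstep)
    t = np.arange(n_win) / sfreq
    e = np.exp(-2j * np.pi * freqs[:, None] * t[None, :]) * np.hanning(n_win)[None, :]
    coef = np.einsum("ncw,fw->ncf", seg, e)  # (trials, channels, bins)
    csd = np.einsum("ncf,ndf->cd", coef, coef.conj()) / (x.shape[0] * len(freqs))
    return csd


def scalar_mv_weights(
    csd: np.ndarray,
    gain: np.ndarray,
    reg: float = 0.05,
    use_real: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-gain scalar beamformer weights and orientations, all voxels at once.

    Parameters
    ----------
    csd : (n_ch, n_ch) covariance / cross-spectrum.
    gain : (n_vox, 3, n_ch) lead field.
    reg : Tikhonov factor — ``C + reg·mean(diag C)·I`` is inverted.

    Returns
    -------
    weights : (n_vox, n_ch) with ``w·l(orientation) = 1`` per voxel.
    orientations : (n_vox, 3) unit vectors maximizing output source power
        (smallest-eigenvalue direction of ``L C⁻¹ Lᵀ``).
    """
    c = np.real(csd) if use_real else np.asarray(csd)
    lam = reg * np.trace(c).real / c.shape[0]
    ci = np.linalg.inv(c + lam * np.eye(c.shape[0]))
    g = np.asarray(gain)
    m = np.einsum("vac,cd,vbd->vab", g, ci, g)  # (n_vox, 3, 3)
    if np.linalg.matrix_rank(m[0]) < 3 and len(m) == 1:
        raise np.linalg.LinAlgError("rank-deficient gain at voxel")
    evals, evecs = np.linalg.eigh(m)
    ori = evecs[:, :, 0]  # smallest eigenvalue -> maximal unit-gain power
    ori = ori / np.linalg.norm(ori, axis=1, keepdims=True)
    lead = np.einsum("va,vac->vc", ori, g)  # (n_vox, n_ch)
    ci_l = lead @ ci.T
    denom = np.einsum("vc,vc->v", ci_l, lead)
    weights = ci_l / denom[:, None]
    return weights, ori


@dataclass
class SourcePowerMap:
    """Per-voxel dB power relative to baseline, per band and window center."""

    grid: SourceGrid
    power_db: np.ndarray  # (n_vox, n_bands, n_centers)
    bands: list[str]
    centers_ms: np.ndarray
    baseline_ms: tuple[float, float] = (-550.0, 0.0)


def source_power_maps(
    data: np.ndarray,
    sfreq: float,
    t0_index: int,
    leadfield: LeadField,
    bands: dict[str, tuple[float, float]] | None = None,
    win_ms: float = 300.0,
    hop_ms: float = 50.0,
    baseline_ms: tuple[float, float] = (-550.0, 0.0),
    reg: float = 0.05,
) -> SourcePowerMap:
    """Beamformer dB power per voxel × band × window for one subject's epochs.

    Weights per band come from the covariance averaged over all windows
    (common spatial filter); power per window is ``w C_w wᵀ``, log-transformed
    and baseline-corrected per voxel and band.
    """
    from .timefreq import window_centers

    bands = bands or BANDS
    centers = window_centers(data.shape[2], t0_index, sfreq, win_ms, hop_ms)
    base_sel = (centers >= baseline_ms[0]) & (centers <= baseline_ms[1])
    if not base_sel.any():
        raise ValueError("no baseline windows available")
    n_vox = leadfield.grid.n_voxels
    power = np.empty((n_vox, len(bands), len(centers)))
    for bi, (_, band) in enumerate(bands.items()):
        csds = [
            window_csd(data, sfreq, t0_index, c, band, win_ms=win_ms) for c in centers
        ]
        w, _ = scalar_mv_weights(np.mean(csds, axis=0), leadfield.gain, reg=reg)
        for wi, csd in enumerate(csds):
            power[:, bi, wi] = np.einsum("vc,cd,vd->v", w, np.real(csd), w)
    logp = 10.0 * np.log10(np.maximum(power, 1e-30))
    power_db = logp - logp[:, :, base_sel].mean(axis=2, keepdims=True)
    return SourcePowerMap(leadfield.grid, power_db, list(bands), centers, baseline_ms)


def snpm_cluster_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray | None,
    grid: SourceGrid,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> tuple[NDClusterResult, np.ndarray]:
    """SnPM-style voxel t test with spatial cluster correction.

    ``maps_a`` (and optionally ``maps_b``) are (n_subjects, n_voxels) scalar
    maps (e.g. one band × window of dB power).  ``maps_b=None`` tests
    against zero change.  Clusters of face-adjacent (6-connectivity) voxels
    are retained when larger than the 95th percentile of the permutation
    maximum-cluster-size distribution.  Returns the cluster result on the
    packed 3-D volume and the per-voxel observed t values.
    """
    a = np.asarray(maps_a, dtype=float)
    d = a if maps_b is None else a - np.asarray(maps_b, dtype=float)
    if d.shape[1] != grid.n_voxels:
        raise ValueError("maps do not match the source grid")
    ijk, shape, _ = grid.volume_index()
    vol = np.zeros((d.shape[0], *shape))
    vol[:, ijk[:, 0], ijk[:, 1], ijk[:, 2]] = d
    res = sign_flip_cluster_nd(vol, n_perm=n_perm, cluster_alpha=cluster_alpha, seed=seed)
    t_vox = res.t_obs[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    return res, t_vox


def cluster_table(res: NDClusterResult, grid: SourceGrid):
    """Significant clusters as a table: peak |t| voxel (MNI mm), size, corrected p."""
    import pandas as pd

    ijk, _, origin = grid.volume_index()
    rows = []
    for c in res.significant:
        idx = np.argwhere(c.indices)
        tvals = res.t_obs[tuple(idx.T)]
        peak = idx[np.argmax(np.abs(tvals))]
        mni = origin + peak * grid.spacing_mm
        rows.append(
            dict(
                peak_x_mm=mni[0], peak_y_mm=mni[1], peak_z_mm=mni[2],
                size_voxels=c.size, p_corrected=c.p_corrected, sign=c.sign,
            )
        )
    return pd.DataFrame(rows)
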