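"""Scalar minimum-variance beamformer: covariance, weights, localization, SnPM."""

import numpy as np
import pytest

from orfi_eeg import beamformer
from orfi_eeg.forward import dipole_potential
from orfi_eeg.synth import pink_noise


def _epochs_with_dipole(montage, rng, n_trials=30, n_times=1400, freq=6.0,
                        src=None, amp=8.0, noise=1.0, window=(300, 300)):
    """Band-limited dipole burst + white noise epochs (µV)."""
    src = np.asarray(src if src is not None else montage.sphere_center + [0, 20, 20], float)
    g = dipole_potential(src, [0.0, 1.0, 1.0], montage)
    g = g / np.max(np.abs(g))
    t = np.arange(n_times) / 1000.0
    center_idx = 700 + window[0]
    env = np.exp(-0.5 * ((np.arange(n_times) - center_idx) / window[1]) ** 2)
    data = rng.normal(scale=noise, size=(n_trials, len(g), n_times))
    for i in range(n_trials):
        carrier = np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        data[i] += np.outer(g, amp * env * carrier)
    return data, src


def test_csd_hermitian_psd(montage):
    rng = np.random.default_rng(0)
    data = rng.normal(size=(10, montage.n_channels, 1400))
    csd = beamformer.window_csd(data, 1000.0, 700, 100.0, (4.0, 7.0))
    np.testing.assert_allclose(csd, csd.conj().T, atol=1e-10)
    ev = np.linalg.eigvalsh(csd)
    assert ev.min() > -1e-8 * ev.max()


def test_csd_white_noise_is_near_diagonal(montage):
    rng = np.random.default_rng(1)
    data = rng.normal(size=(300, 24, 1400))
    csd = np.real(beamformer.window_csd(data[:, :, :], 1000.0, 700, 0.0, (8.0, 12.0)))
    d = np.diag(csd)
    off = csd - np.diag(d)
    assert d.std() / d.mean() < 0.2
    assert np.abs(off).max() < 0.25 * d.mean()


def test_csd_single_source_rank_one(montage):
    rng = np.random.default_rng(2)
    data, _ = _epochs_with_dipole(montage, rng, n_trials=20, noise=0.01)
    csd = np.real(beamformer.window_csd(data, 1000.0, 700, 300.0, (4.0, 8.0)))
    ev = np.sort(np.linalg.eigvalsh(csd))[::-1]
    assert ev[0] / ev[1] > 50


def test_window_outside_epoch_rejected(montage):
    with pytest.raises(ValueError):
        beamformer.window_csd(np.zeros((3, 5, 1000)), 1000.0, 500, 600.0, (4.0, 7.0))


def test_unit_gain_constraint(coarse_leadfield):
    rng = np.random.default_rng(3)
    n_ch = coarse_leadfield.gain.shape[2]
    x = rng.normal(size=(n_ch, 500))
    csd = x @ x.T / 500
    w, ori = beamformer.scalar_mv_weights(csd, coarse_leadfield.gain)
    lead = np.einsum("va,vac->vc", ori, coarse_leadfield.gain)
    np.testing.assert_allclose(np.einsum("vc,vc->v", w, lead), 1.0, atol=1e-9)


def test_identity_covariance_gives_pseudoinverse_weights(coarse_leadfield):
    """With C = I the unit-gain weights reduce to l / (l'l)."""
    n_ch = coarse_leadfield.gain.shape[2]
    w, ori = beamformer.scalar_mv_weights(np.eye(n_ch), coarse_leadfield.gain, reg=0.0)
    lead = np.einsum("va,vac->vc", ori, coarse_leadfield.gain)
    expected = lead / np.einsum("vc,vc->v", lead, lead)[:, None]
    np.testing.assert_allclose(w, expected, atol=1e-9)


def test_single_dipole_localized_at_truth(montage, coarse_leadfield):
    """Output power at the source voxel beats every voxel 2+ grid steps away."""
    rng = np.random.default_rng(4)
    vox = coarse_leadfield.grid.voxels_mm
    src = vox[coarse_leadfield.grid.nearest(montage.sphere_center + [10, 20, 20])]
    data, _ = _epochs_with_dipole(montage, rng, n_trials=40, src=src, amp=10.0, noise=1.0)
    csd = beamformer.window_csd(data, 1000.0, 700, 300.0, (4.0, 8.0))
    w, _ = beamformer.scalar_mv_weights(csd, coarse_leadfield.gain)
    p = np.einsum("vc,cd,vd->v", w, np.real(csd), w)
    peak = vox[np.argmax(p)]
    dist = np.linalg.norm(vox - src, axis=1)
    far = dist >= 2 * coarse_leadfield.grid.spacing_mm
    assert p.max() >= p[far].max()
    assert np.linalg.norm(peak - src) <= 2 * coarse_leadfield.grid.spacing_mm


def test_output_power_monotone_in_regularization(montage, coarse_leadfield):
    """Unit-gain MV output power is minimal at λ=0 and non-decreasing in λ.

    The λ=0 filter minimizes output variance subject to w·l = 1, so any
    regularized filter passes at least as much power; weights also vary
    continuously with λ.
    """
    rng = np.random.default_rng(5)
    src = coarse_leadfield.grid.voxels_mm[coarse_leadfield.grid.nearest(
        montage.sphere_center + [0, 20, 20])]
    data, _ = _epochs_with_dipole(montage, rng, n_trials=30, src=src, amp=10.0)
    csd = beamformer.window_csd(data, 1000.0, 700, 300.0, (4.0, 8.0))
    v = coarse_leadfield.grid.nearest(src)
    powers, weights = [], []
    for lam in (0.0, 0.01, 0.05, 0.2, 1.0):
        w, _ = beamformer.scalar_mv_weights(csd, coarse_leadfield.gain, reg=lam)
        powers.append(float(np.einsum("c,cd,d->", w[v], np.real(csd), w[v])))
        weights.append(w[v])
    assert all(b >= a * 0.999 for a, b in zip(powers, powers[1:]))
    # continuity: nearby λ give nearby weights
    w_a, _ = beamformer.scalar_mv_weights(csd, coarse_leadfield.gain, reg=0.05)
    w_b, _ = beamformer.scalar_mv_weights(csd, coarse_leadfield.gain, reg=0.0500001)
    assert np.linalg.norm(w_a[v] - w_b[v]) / np.linalg.norm(w_a[v]) < 1e-4


def test_source_power_maps_scale_invariant_and_stationary(montage, coarse_leadfield):
    rng = np.random.default_rng(6)
    n_ch = montage.n_channels
    data = pink_noise(60 * n_ch, 1400, 1.0, rng).reshape(60, n_ch, 1400).astype(float) * 5
    bands = {"theta": (4.0, 7.0)}
    m1 = beamformer.source_power_maps(data, 1000.0, 700, coarse_leadfield, bands=bands)
    # stationary noise: ~0 dB up to Monte-Carlo scatter of the window estimates
    assert np.abs(m1.power_db).mean() < 0.7
    assert np.abs(m1.power_db).max() < 3.0
    m2 = beamformer.source_power_maps(2.0 * data, 1000.0, 700, coarse_leadfield, bands=bands)
    np.testing.assert_allclose(m1.power_db, m2.power_db, atol=1e-7)


def test_injected_burst_localized_in_db_map(montage, coarse_leadfield):
    """Theta burst at a grid voxel: the max-dB voxel is within one grid step."""
    rng = np.random.default_rng(7)
    vox = coarse_leadfield.grid.voxels_mm
    src = vox[coarse_leadfield.grid.nearest(montage.sphere_center + [-20, 10, 20])]
    noise = pink_noise(25 * montage.n_channels, 1400, 1.0, rng).reshape(
        25, montage.n_channels, 1400).astype(float) * 2
    burst, _ = _epochs_with_dipole(montage, rng, n_trials=25, src=src, amp=10.0, noise=0.0)
    data = noise + burst
    m = beamformer.source_power_maps(
        data, 1000.0, 700, coarse_leadfield, bands={"theta": (4.0, 7.0)})
    wi = int(np.argmin(np.abs(m.centers_ms - 300.0)))
    peak = vox[np.argmax(m.power_db[:, 0, wi])]
    assert np.linalg.norm(peak - src) <= 1.5 * coarse_leadfield.grid.spacing_mm


def test_snpm_null_and_effect(coarse_leadfield):
    rng = np.random.default_rng(8)
    grid = coarse_leadfield.grid
    null = rng.normal(size=(15, grid.n_voxels))
    res, t = beamformer.snpm_cluster_test(null, null.copy(), grid, n_perm=150, seed=0)
    assert res.significant == []
    np.testing.assert_array_equal(t, 0)
    # +1 dB in a compact voxel ball against moderate noise
    center = grid.voxels_mm[grid.nearest([0.0, 0.0, 60.0])]
    ball = np.linalg.norm(grid.voxels_mm - center, axis=1) <= 1.6 * grid.spacing_mm
    a = rng.normal(scale=0.5, size=(15, grid.n_voxels))
    a[:, ball] += 1.0
    b = rng.normal(scale=0.5, size=(15, grid.n_voxels))
    res2, t2 = beamformer.snpm_cluster_test(a, b, grid, n_perm=300, seed=1)
    mask = res2.mask()
    ijk, _, _ = grid.volume_index()
    hit = mask[ijk[ball, 0], ijk[ball, 1], ijk[ball, 2]]
    assert hit.mean() >= 0.5
    table = beamformer.cluster_table(res2, grid)
    assert (table["p_corrected"] <= 0.05).any()


def test_bands_cover_3_to_45_without_overlap():
    edges = sorted(beamformer.BANDS.values())
    assert edges[0][0] >= 3.0 and edges[-1][1] <= 45.0
    for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
        assert hi1 < lo2
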