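"""Independent reference implementations used only by the tests.

Deliberately written with explicit loops / series sums and textbook
formulas, not sharing code paths with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre, lpmv


def sphere_potential_series(
    position_mm, moment_nam, montage, order: int = 150, sigma: float = 0.33
) -> np.ndarray:
    """Truncated Legendre-series surface potential (µV), not average-referenced.

    V = 1/(4πσR²) Σ_n (2n+1)/n f^(n−1) [n q_r P_n(x) + q_t P_n¹(x)]
    with the positive (no Condon–Shortley phase) associated Legendre
    convention.
    """
    c = montage.sphere_center
    r0 = (np.asarray(position_mm, float) - c) / 1000.0
    q = np.asarray(moment_nam, float) * 1e-9
    re = (montage.positions - c) / 1000.0
    R = montage.sphere_radius / 1000.0
    b = np.linalg.norm(r0)
    reh = re / np.linalg.norm(re, axis=1, keepdims=True)
    if b < 1e-12:
        return 3.0 * (reh @ q) / (4.0 * np.pi * sigma * R**2) * 1e6
    r0h = r0 / b
    x = np.clip(reh @ r0h, -1.0, 1.0)
    qr = q @ r0h
    et = reh - x[:, None] * r0h
    nrm = np.linalg.norm(et, axis=1)
    et = np.divide(et, nrm[:, None], out=np.zeros_like(et), where=nrm[:, None] > 1e-12)
    qte = et @ q
    f = b / R
    v = np.zeros(len(re))
    for n in range(1, order + 1):
        pn = eval_legendre(n, x)
        pn1 = -lpmv(1, n, x)  # positive convention
        v += (2 * n + 1) / n * f ** (n - 1) * (n * qr * pn + qte * pn1)
    return v / (4.0 * np.pi * sigma * R**2) * 1e6


def rm_anova_2x3_oracle(y: np.ndarray) -> dict:
    """Textbook sums-of-squares two-way repeated-measures ANOVA (loops).

    y: (n_subjects, a, b).  Returns F, df, GG epsilon and GG-corrected p per
    effect.  Epsilon uses Box's formula on the effect-projected covariance.
    """
    from scipy import stats

    n, a, b = y.shape
    gm = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    m_ab = y.mean(axis=0)
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)

    ss_a = n * b * sum((m_a[i] - gm) ** 2 for i in range(a))
    ss_b = n * a * sum((m_b[j] - gm) ** 2 for j in range(b))
    ss_ab = n * sum(
        (m_ab[i, j] - m_a[i] - m_b[j] + gm) ** 2 for i in range(a) for j in range(b)
    )
    ss_as = b * sum(
        (m_as[s, i] - m_a[i] - m_s[s] + gm) ** 2 for s in range(n) for i in range(a)
    )
    ss_bs = a * sum(
        (m_bs[s, j] - m_b[j] - m_s[s] + gm) ** 2 for s in range(n) for j in range(b)
    )
    ss_abs = sum(
        (
            y[s, i, j]
            - m_ab[i, j]
            - m_as[s, i]
            - m_bs[s, j]
            + m_a[i]
            + m_b[j]
            + m_s[s]
            - gm
        )
        ** 2
        for s in range(n)
        for i in range(a)
        for j in range(b)
    )

    def box_eps(projected: np.ndarray, d: int) -> float:
        """Box/GG epsilon from the covariance of effect-projected subject data."""
        if d == 1:
            return 1.0
        cov = np.cov(projected.T, ddof=1)
        lam = np.linalg.eigvalsh(cov)
        lam = lam[lam > 1e-12 * lam.max()]
        return float(lam.sum() ** 2 / (d * (lam**2).sum()))

    # effect-projected per-subject data (centered within the effect space)
    pa = m_as - m_as.mean(axis=1, keepdims=True)  # (n, a)
    pb = m_bs - m_bs.mean(axis=1, keepdims=True)  # (n, b)
    yc = y - m_as[:, :, None] - m_bs[:, None, :] + m_s[:, None, None]
    pab = yc.reshape(n, a * b)

    out = {}
    for name, ss_eff, ss_err, d, proj in [
        ("main_condition", ss_a, ss_as, a - 1, pa),
        ("main_trial", ss_b, ss_bs, b - 1, pb),
        ("interaction", ss_ab, ss_abs, (a - 1) * (b - 1), pab),
    ]:
        df1, df2 = d, d * (n - 1)
        f = (ss_eff / df1) / (ss_err / df2)
        eps = box_eps(proj, d)
        out[name] = dict(
            F=f, df=(df1, df2), epsilon=eps,
            p_gg=float(stats.f.sf(f, df1 * eps, df2 * eps)),
        )
    return out


def stft_power_bruteforce(
    x: np.ndarray, sfreq: float, t0_index: int, freqs, centers_ms, win_ms: float = 300.0
) -> np.ndarray:
    """Direct per-window, per-frequency Hanning DFT power (nested loops).

    x: (n_times,) single signal.  Returns (n_freqs, n_centers).
    """
    n_win = int(round(win_ms / 1000.0 * sfreq))
    w = np.hanning(n_win)
    out = np.zeros((len(freqs), len(centers_ms)))
    for ci, c_ms in enumerate(centers_ms):
        start = int(round(c_ms / 1000.0 * sfreq)) + t0_index - n_win // 2
        seg = x[start : start + n_win] * w
        for fi, f in enumerate(freqs):
            ex = np.exp(-2j * np.pi * f * np.arange(n_win) / sfreq)
            out[fi, ci] = np.abs(np.sum(seg * ex)) ** 2
    return out
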