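"""Mass-univariate and cluster-permutation statistics for ERP analyses.

Three layers:

* a vectorized two-way (2 conditions × 3 trial types) repeated-measures
  ANOVA evaluated independently at every electrode × timeframe, with
  Greenhouse–Geisser correction applied where Mauchly's test indicates a
  sphericity violation;
* an extent filter keeping only effects significant at ``p < alpha`` for at
  least ``min_ms`` over at least ``min_electrodes`` contiguous electrodes;
* a paired-t temporal cluster-permutation test (sign-flip randomization,
  maximum-cluster-size null, clusters retained when larger than the 95th
  percentile of the permutation distribution).

The sign-flip permutation engine is shared with the time–frequency and
source modules, which cluster in 2-D and 3-D via ``scipy.ndimage``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse, stats
from scipy.sparse.csgraph import connected_components

# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class StatMap:
    """Per-point F/p maps for one ANOVA effect."""

    effect: str  # "main_condition" | "main_trial" | "interaction"
    F: np.ndarray
    p: np.ndarray  # GG-corrected where Mauchly indicates a violation
    p_uncorrected: np.ndarray
    p_gg: np.ndarray  # always GG-corrected
    epsilon: np.ndarray  # raw Greenhouse–Geisser epsilon (1.0 where k == 2)
    mauchly_p: np.ndarray
    sphericity_violated: np.ndarray
    df: tuple[float, float]
    partial_eta_sq: np.ndarray | None = None


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal basis of the subspace orthogonal to the constant."""
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    return c.T


def _gg_and_mauchly(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greenhouse–Geisser epsilon and Mauchly p from orthonormal effect scores.

    scores: (n_subjects, k-1, ...) within-subject contrast scores.
    """
    n, p_ = scores.shape[0], scores.shape[1]
    if p_ == 1:
        shape = scores.shape[2:]
        return np.ones(shape), np.ones(shape)
    zc = scores - scores.mean(axis=0, keepdims=True)
    cov = np.einsum("si...,sj...->ij...", zc, zc) / (n - 1)
    tr = np.einsum("ii...->...", cov)
    tr2 = np.einsum("ij...,ji...->...", cov, cov)
    eps = tr**2 / (p_ * np.maximum(tr2, 1e-300))
    eps = np.clip(eps, 1.0 / p_, 1.0)
    # Mauchly's W with the chi-square approximation
    if p_ == 2:
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    else:  # pragma: no cover — the 2×3 design only needs p_ <= 2
        det = np.linalg.det(np.moveaxis(cov, (0, 1), (-2, -1)))
    w = np.clip(det / np.maximum((tr / p_) ** p_, 1e-300), 1e-300, 1.0)
    mult = (n - 1) - (2 * p_**2 + p_ + 2) / (6.0 * p_)
    chi2 = -mult * np.log(w)
    df_m = p_ * (p_ + 1) // 2 - 1
    mauchly_p = stats.chi2.sf(chi2, df_m)
    return eps, mauchly_p


def _effect_stats(
    scores: np.ndarray,
    effect: str,
    n: int,
    mauchly_alpha: float = 0.05,
    scale_sq: np.ndarray | float = 1.0,
) -> StatMap:
    """F test that the mean of within-subject contrast scores is zero.

    For orthonormal contrast scores Z (n × p_ × points),
    SS_effect = n·|mean Z|² and SS_error = Σ|Z − mean Z|², giving the
    standard univariate repeated-measures F with df (p_, p_(n−1)).
    """
    p_ = scores.shape[1]
    m = scores.mean(axis=0)
    ss_eff = n * (m**2).sum(axis=0)
    ss_err = ((scores - m) ** 2).sum(axis=(0, 1))
    # cells numerically identical across levels: report a null effect instead
    # of amplifying float cancellation noise in a 0/0 ratio
    degenerate = (ss_eff + ss_err) <= 1e-20 * n * p_ * np.asarray(scale_sq)
    ss_eff = np.where(degenerate, 0.0, ss_eff)
    df1, df2 = p_, p_ * (n - 1)
    F = (ss_eff / df1) / np.maximum(ss_err / df2, 1e-300)
    F = np.where(degenerate, 0.0, F)
    eps, mauchly_p = _gg_and_mauchly(scores)
    p_unc = stats.f.sf(F, df1, df2)
    p_gg = stats.f.sf(F, df1 * eps, df2 * eps)
    violated = mauchly_p < mauchly_alpha
    return StatMap(
        effect=effect,
        F=F,
        p=np.where(violated, p_gg, p_unc),
        p_uncorrected=p_unc,
        p_gg=p_gg,
        epsilon=eps,
        mauchly_p=mauchly_p,
        sphericity_violated=violated,
        df=(df1, df2),
        partial_eta_sq=ss_eff / np.maximum(ss_eff + ss_err, 1e-300),
    )


def pointwise_rm_anova(cell_means: np.ndarray) -> dict[str, StatMap]:
    """2 × 3 repeated-measures ANOVA at every trailing point.

    Parameters
    ----------
    cell_means : array (n_subjects, 2, 3, ...) — per-subject condition ×
        trial-type means; trailing axes are arbitrary (electrodes × time,
        frequencies, or nothing for scalar RTs).
    """
    y = np.asarray(cell_means, dtype=float)
    if y.ndim < 3 or y.shape[1] != 2 or y.shape[2] != 3:
        raise ValueError("cell_means must be (n_subjects, 2, 3, ...)")
    n = y.shape[0]
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    if not np.isfinite(y).all():
        raise ValueError("cell means contain non-finite values (missing cell?)")
    ca = _orthonormal_contrasts(2)  # (1, 2)
    cb = _orthonormal_contrasts(3)  # (2, 3)
    za = np.einsum("ia,na...->ni...", ca, y.mean(axis=2))
    zb = np.einsum("jb,nb...->nj...", cb, y.mean(axis=1))
    cab = np.einsum("ia,jb->ijab", ca, cb).reshape(2, 6)
    zab = np.einsum("kc,nc...->nk...", cab, y.reshape(n, 6, *y.shape[3:]))
    scale_sq = (y**2).mean(axis=(0, 1, 2)) + 1e-300
    return {
        "main_condition": _effect_stats(za, "main_condition", n, scale_sq=scale_sq),
        "main_trial": _effect_stats(zb, "main_trial", n, scale_sq=scale_sq),
        "interaction": _effect_stats(zab, "interaction", n, scale_sq=scale_sq),
    }


def rt_rm_anova(rt_cells: np.ndarray) -> dict:
    """Behavioral 2 × 3 ANOVA on per-subject RT cell means with post hocs.

    Returns omnibus effects (F, GG-corrected p, partial eta-squared) and
    Bonferroni-corrected paired post-hoc t-tests between trial types within
    each condition with Cohen's d (mean difference / SD of differences).
    """
    y = np.asarray(rt_cells, dtype=float)
    if y.ndim != 3:
        y = y.reshape(y.shape[0], 2, 3)
    maps = pointwise_rm_anova(y[..., None])
    omnibus = {
        k: dict(
            F=float(v.F[0]),
            p=float(v.p[0]),
            epsilon=float(v.epsilon[0]),
            df=v.df,
            partial_eta_sq=float(v.partial_eta_sq[0]),
        )
        for k, v in maps.items()
    }
    rows = []
    pairs = [(0, 1, "SAME-SIMI"), (0, 2, "SAME-DIFF"), (1, 2, "SIMI-DIFF")]
    n_comp = len(pairs) * 2
    for ci, cname in enumerate(("identical", "semantical")):
        for i, j, label in pairs:
            d = y[:, ci, i] - y[:, ci, j]
            t, p = stats.ttest_rel(y[:, ci, i], y[:, ci, j])
            rows.append(
                dict(
                    condition=cname,
                    contrast=label,
                    t=float(t),
                    p=float(p),
                    p_bonferroni=float(min(1.0, p * n_comp)),
                    cohen_d=float(d.mean() / d.std(ddof=1)) if d.std(ddof=1) > 0 else 0.0,
                )
            )
    return {"omnibus": omnibus, "posthoc": pd.DataFrame(rows)}


# ---------------------------------------------------------------------------
# extent filtering (p < alpha, >= min_ms, >= min_electrodes contiguous)
# ---------------------------------------------------------------------------


@dataclass
class SignificanceMask:
    mask: np.ndarray  # (n_electrodes, n_times) bool
    alpha: float
    min_ms: float
    min_electrodes: int


def _prune_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = mask.copy()
    for row in out:
        lab, n = ndimage.label(row)
        if not n:
            continue
        sizes = ndimage.sum_labels(np.ones_like(row, dtype=float), lab, index=np.arange(1, n + 1))
        for k in np.flatnonzero(sizes < min_len):
            row[lab == k + 1] = False
    return out


def _prune_small_components(mask: np.ndarray, adjacency: np.ndarray, min_elec: int) -> np.ndarray:
    out = mask.copy()
    adj = sparse.csr_matrix(adjacency)
    for t in range(out.shape[1]):
        active = np.flatnonzero(out[:, t])
        if len(active) == 0:
            continue
        if len(active) < min_elec:
            out[:, t] = False
            continue
        _, labels = connected_components(adj[np.ix_(active, active)], directed=False)
        sizes = np.bincount(labels)
        out[active[sizes[labels] < min_elec], t] = False
    return out


def extent_filter(
    stat: StatMap,
    adjacency: np.ndarray,
    alpha: float = 0.01,
    min_ms: float = 20.0,
    min_electrodes: int = 5,
    sfreq: float = 1000.0,
) -> SignificanceMask:
    """Keep only supra-threshold regions meeting both extent criteria.

    The temporal (≥ ``min_ms``) and spatial (≥ ``min_electrodes`` contiguous
    electrodes at every retained timeframe) rules are applied alternately to
    a fixed point, so every surviving point satisfies both jointly.
    """
    if adjacency.shape[0] != stat.p.shape[0]:
        raise ValueError("adjacency size does not match the electrode axis")
    n_comp, _ = connected_components(sparse.csr_matrix(adjacency), directed=False)
    if n_comp > 0.2 * adjacency.shape[0]:
        import warnings

        warnings.warn("electrode adjacency is heavily disconnected", stacklevel=2)
    min_len = int(round(min_ms * sfreq / 1000.0))
    mask = stat.p < alpha
    while True:
        new = _prune_small_components(mask, adjacency, min_electrodes)
        new = _prune_short_runs(new, min_len)
        if np.array_equal(new, mask):
            break
        mask = new
    return SignificanceMask(mask, alpha, min_ms, min_electrodes)


# ---------------------------------------------------------------------------
# cluster time courses and cluster-permutation paired t
# ---------------------------------------------------------------------------


def cluster_timecourse(erp: np.ndarray, montage, cluster_set: str) -> np.ndarray:
    """Mean over the five member electrodes of a named cluster set.

    ``erp`` has the electrode axis at position −2 (…, electrodes, time).
    """
    idx = montage.cluster_indices(cluster_set)
    return np.asarray(erp)[..., idx, :].mean(axis=-2)


@dataclass
class Cluster:
    start: int  # first supra-threshold frame
    end: int  # last supra-threshold frame (inclusive)
    size: int
    p_corrected: float
    sign: int  # sign of mean t inside the cluster


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    threshold: float
    n_perm: int
    null_percentile_95: float
    null_max_sizes: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.size > self.null_percentile_95]

    def mask(self) -> np.ndarray:
        out = np.zeros_like(self.t_obs, dtype=bool)
        for c in self.significant:
            out[c.start : c.end + 1] = True
        return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, inclusive end) of each True run in a 1-D mask."""
    idx = np.flatnonzero(np.diff(np.r_[False, mask, False].astype(np.int8)))
    return [(int(s), int(e - 1)) for s, e in zip(idx[::2], idx[1::2])]


def max_run_lengths(supra: np.ndarray) -> np.ndarray:
    """Maximum run of True per row of a 2-D boolean array (vectorized)."""
    c = np.cumsum(supra, axis=1)
    reset = np.where(~supra, c, 0)
    m = np.maximum.accumulate(reset, axis=1)
    return np.maximum(c - m, 0).max(axis=1)


def paired_t_cluster_perm(
    series_a: np.ndarray,
    series_b: np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Paired-t temporal cluster test with sign-flip permutation correction.

    Contiguous frames whose two-sided paired ``|t|`` exceeds the
    ``cluster_alpha`` criterion form clusters.  The null distribution of
    the maximum cluster size (in frames) is built from random within-subject
    sign flips of the difference waves; a cluster is significant when its
    size exceeds the 95th percentile of that distribution.  Its p-value is
    the ``(1 + #{max ≥ size}) / (n_perm + 1)`` exceedance fraction.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have identical shape")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n, _ = a.shape
    d = a - b
    ss = (d**2).sum(axis=0)
    mean = d.mean(axis=0)
    var = (ss - n * mean**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_obs = mean / np.sqrt(var / n)
    t_obs = np.nan_to_num(t_obs)
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1)
    supra = np.abs(t_obs) > thr

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    mean_p = signs @ d / n
    var_p = (ss[None, :] - n * mean_p**2) / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_p = mean_p / np.sqrt(var_p / n)
    t_p = np.nan_to_num(t_p)
    null_max = max_run_lengths(np.abs(t_p) > thr)
    perc95 = float(np.percentile(null_max, 95))

    clusters = []
    for s, e in _runs(supra):
        size = e - s + 1
        p_corr = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
        sign = int(np.sign(t_obs[s : e + 1].mean()))
        clusters.append(Cluster(s, e, size, float(p_corr), sign))
    return ClusterResult(clusters, t_obs, float(thr), n_perm, perc95, null_max)


def null_fwer_simulation(
    n_experiments: int = 1000,
    n_subjects: int = 20,
    n_times: int = 701,
    n_perm: int = 500,
    cluster_alpha: float = 0.05,
    noise_exponent: float = 1.0,
    seed: int = 0,
) -> float:
    """Family-wise false-positive rate of the temporal cluster test under the null.

    Each simulated experiment draws two identically distributed conditions of
    1/f-correlated noise per subject and runs :func:`paired_t_cluster_perm`;
    the return value is the fraction of experiments declaring at least one
    significant cluster (size above the 95th percentile of the permutation
    maximum-cluster-size null).
    """
    from .synth import pink_noise

    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_experiments):
        noise = pink_noise(2 * n_subjects, n_times, noise_exponent, rng)
        a = noise[:n_subjects].astype(float)
        b = noise[n_subjects:].astype(float)
        res = paired_t_cluster_perm(
            a, b, n_perm=n_perm, cluster_alpha=cluster_alpha,
            seed=int(rng.integers(2**31)),
        )
        if res.significant:
            hits += 1
    return hits / n_experiments


# ---------------------------------------------------------------------------
# N-D sign-flip cluster engine (shared by the time–frequency and source maps)
# ---------------------------------------------------------------------------


@dataclass
class NDCluster:
    indices: np.ndarray  # boolean mask over the map
    size: int
    p_corrected: float
    sign: int
    bounding_box: tuple[tuple[int, int], ...]


@dataclass
class NDClusterResult:
    clusters: list[NDCluster]
    t_obs: np.ndarray
    threshold: float
    n_perm: int
    null_percentile_95: float

    @property
    def significant(self) -> list[NDCluster]:
        return [c for c in self.clusters if c.size > self.null_percentile_95]

    def mask(self) -> np.ndarray:
        out = np.zeros_like(self.t_obs, dtype=bool)
        for c in self.significant:
            out |= c.indices
        return out


def sign_flip_cluster_nd(
    diffs: np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
    structure: np.ndarray | None = None,
) -> NDClusterResult:
    """One-sample (paired-difference) t cluster test over an N-D map.

    ``diffs`` is (n_subjects, *map_shape).  Supra-threshold two-sided |t|
    points are grouped into face-adjacent components; correction uses the
    permutation maximum-cluster-size distribution as in the temporal test.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.shape[0]
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    map_shape = d.shape[1:]
    flat = d.reshape(n, -1)
    ss = (flat**2).sum(axis=0)
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, n - 1)
    if structure is None:
        structure = ndimage.generate_binary_structure(len(map_shape), 1)

    def tmap(mean_flat: np.ndarray) -> np.ndarray:
        var = (ss - n * mean_flat**2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean_flat / np.sqrt(var / n)
        return np.nan_to_num(t).reshape(map_shape)

    t_obs = tmap(flat.mean(axis=0))
    supra = np.abs(t_obs) > thr

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    ones = None
    for i in range(n_perm):
        signs = rng.integers(0, 2, size=n) * 2 - 1
        lab, n_lab = ndimage.label(np.abs(tmap(signs @ flat / n)) > thr, structure=structure)
        if n_lab:
            if ones is None or ones.shape != lab.shape:
                ones = np.ones_like(lab, dtype=float)
            null_max[i] = ndimage.sum_labels(ones, lab, index=np.arange(1, n_lab + 1)).max()
    perc95 = float(np.percentile(null_max, 95))

    clusters = []
    lab, n_lab = ndimage.label(supra, structure=structure)
    for k in range(1, n_lab + 1):
        idx = lab == k
        size = int(idx.sum())
        p_corr = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
        sign = int(np.sign(t_obs[idx].mean()))
        bbox = tuple((int(ax.min()), int(ax.max())) for ax in np.nonzero(idx))
        clusters.append(NDCluster(idx, size, float(p_corr), sign, bbox))
    return NDClusterResult(clusters, t_obs, float(thr), n_perm, perc95)
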