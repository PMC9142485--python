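"""Synthetic multi-subject epoched EEG with the structure the analysis assumes.

Every effect is injected through the spherical-head forward model: ERP
components are Gaussian-envelope dipole waveforms, oscillatory effects are
amplitude-modulated sinusoidal dipole sources with random per-trial phase
(so they appear in induced power, not in the ERP), and the background is
1/f ("pink") noise, partly channel-specific and partly mixed through random
superficial sources to give realistic spatial correlation.  Occasional
high-amplitude artifact epochs and flat bad channels exercise the
rejection/interpolation stages.

The default preset encodes the study conditions this package analyses:
22 subjects, 2 conditions × 3 trial types, 56 epochs per cell at 1000 Hz
(−700..+700 ms around outcome onset, 156 channels), with a frontal
positivity at ~200–330 ms, a central negativity at ~350 ms and a
centro-posterior positivity at ~400–600 ms for switch-signalling outcomes,
plus a frontocentral theta increase and a centroparietal beta suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .forward import dipole_potential
from .montage import Montage, default_montage

CELLS: tuple[tuple[str, str], ...] = tuple(
    (cond, tt) for cond in ("identical", "semantical") for tt in ("SAME", "SIMI", "DIFF")
)
#: cells whose outcome signals a switch on the next trial
SWITCH_CELLS = (("identical", "SIMI"), ("identical", "DIFF"), ("semantical", "DIFF"))


@dataclass
class ERPComponent:
    """Phase-locked Gaussian-envelope dipole component.

    ``amplitude_uv`` maps cells to the peak scalp amplitude (µV at the
    component's best channel); unlisted cells get zero.
    """

    name: str
    source_mm: tuple[float, float, float]
    orientation: tuple[float, float, float]
    latency_ms: float
    width_ms: float  # Gaussian SD of the envelope
    amplitude_uv: dict[tuple[str, str], float]


@dataclass
class OscComponent:
    """Band-limited dipole oscillation with amplitude modulation.

    The envelope is ``base + Σ_cell gain·gauss(center, width)`` (clipped at
    zero); phase is randomized per trial so modulations show up as induced
    power.  ``base_uv > 0`` with negative gains models suppression of an
    ongoing rhythm.
    """

    name: str
    source_mm: tuple[float, float, float]
    orientation: tuple[float, float, float]
    freq_hz: float
    center_ms: float
    width_ms: float  # Gaussian SD of the modulation window
    base_uv: float
    gain_uv: dict[tuple[str, str], float]


@dataclass
class EffectSpec:
    """Full description of one synthetic study."""

    n_subjects: int = 22
    epochs_per_cell: int = 56
    sfreq: float = 1000.0
    n_times: int = 1400
    t0_index: int = 700  # outcome onset sample (epoch −700..+700 ms)
    erp_components: list[ERPComponent] = field(default_factory=list)
    osc_components: list[OscComponent] = field(default_factory=list)
    noise_sd_uv: float = 10.0
    noise_exponent: float = 1.0
    noise_spatial_mix: float = 0.5  # variance fraction routed through shared sources
    n_noise_sources: int = 30
    artifact_rate: float = 0.07
    artifact_amp_uv: float = 160.0
    between_subject_sd: float = 0.3  # SD of log-normal amplitude jitter
    n_bad_channels: int = 1

    def validate(self, montage: Montage) -> None:
        if self.epochs_per_cell < 1:
            raise ValueError("epochs_per_cell must be >= 1")
        dur = self.n_times / self.sfreq * 1000.0
        for c in self.erp_components:
            if not (-self.t0_index / self.sfreq * 1000.0 <= c.latency_ms <= dur):
                raise ValueError(f"component {c.name}: latency outside the epoch")
            if c.width_ms <= 0:
                raise ValueError(f"component {c.name}: width must be positive")
        r = montage.sphere_radius
        for c in [*self.erp_components, *self.osc_components]:
            ecc = np.linalg.norm(np.asarray(c.source_mm) - montage.sphere_center)
            if ecc >= 0.9 * r:
                raise ValueError(f"component {c.name}: source outside the brain mask")


def _radial_source(
    montage: Montage, clusters: tuple[str, ...], depth: float = 0.55
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Radially oriented source beneath the centroid of one or more cluster sets."""
    dirs = []
    for name in clusters:
        cen = montage.positions[montage.cluster_indices(name)].mean(axis=0)
        d = cen - montage.sphere_center
        dirs.append(d / np.linalg.norm(d))
    d = np.mean(dirs, axis=0)
    d /= np.linalg.norm(d)
    src = montage.sphere_center + d * depth * montage.sphere_radius
    return tuple(src), tuple(d)


def default_effect_spec(montage: Montage | None = None, **overrides) -> EffectSpec:
    """The default study preset (see module docstring).

    Effect sources sit radially beneath the electrode clusters they are
    meant to drive, so the cluster-averaged waveforms carry most of the
    injected amplitude.  Amplitudes are in scalp µV at the source's best
    channel and were chosen so that a 22-subject study shows the switch vs
    non-switch pattern clearly against the 10 µV 1/f background.
    """
    montage = montage or default_montage()
    sw, nsw = SWITCH_CELLS, [c for c in CELLS if c not in SWITCH_CELLS]

    def amp(switch_val: float, same_val: float = 0.0, simi_sem_val: float | None = None):
        d = {c: switch_val for c in sw}
        for c in nsw:
            d[c] = (
                simi_sem_val
                if (c == ("semantical", "SIMI") and simi_sem_val is not None)
                else same_val
            )
        return d

    fr_src, fr_ori = _radial_source(montage, ("frontal",))
    ce_src, ce_ori = _radial_source(montage, ("central",))
    po_src, po_ori = _radial_source(montage, ("posterior",))
    fc_src, fc_ori = _radial_source(montage, ("frontal", "central"))
    cp_src, cp_ori = _radial_source(montage, ("central", "posterior"))

    erps = [
        ERPComponent(
            "visual_p1", (0.0, -75.0, 10.0), (0.0, -1.0, 0.3), 120.0, 25.0,
            {c: 3.0 for c in CELLS},
        ),
        ERPComponent(
            "frontal_switch_positivity", fr_src, fr_ori, 265.0, 45.0,
            amp(4.0, -1.5, 0.0),
        ),
        ERPComponent("central_negativity", ce_src, ce_ori, 350.0, 35.0, amp(-2.0, 0.0)),
        ERPComponent("late_positivity", po_src, po_ori, 500.0, 80.0, amp(4.0, 1.5, 1.5)),
        ERPComponent(
            "late_positivity_central", ce_src, ce_ori, 520.0, 80.0, amp(2.5, 0.8, 0.8)
        ),
    ]
    oscs = [
        OscComponent(
            "frontocentral_theta", fc_src, fc_ori, 5.0, 350.0, 150.0,
            base_uv=0.0, gain_uv=amp(8.0, 1.5),
        ),
        OscComponent(
            "centroparietal_beta", cp_src, cp_ori, 20.0, 475.0, 80.0,
            base_uv=3.0, gain_uv=amp(-1.5, -0.5),
        ),
    ]
    spec = EffectSpec(erp_components=erps, osc_components=oscs)
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


@dataclass
class EpochSet:
    """Trials × channels × time epochs in µV for one subject."""

    data: np.ndarray  # (n_trials, n_channels, n_times) float32, µV
    labels: pd.DataFrame  # columns: subject, condition, trial_type, artifact
    montage: Montage
    sfreq: float = 1000.0
    t0_index: int = 700
    subject: int = 0
    bad_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.data):
            raise ValueError("label count must equal trial count")

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.data.shape[2]) - self.t0_index) / self.sfreq * 1000.0

    def cell(self, condition: str, trial_type: str) -> np.ndarray:
        m = (self.labels["condition"] == condition) & (self.labels["trial_type"] == trial_type)
        return self.data[m.to_numpy()]

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=self.data, compression="gzip", shuffle=True)
            fh.attrs["sfreq"] = self.sfreq
            fh.attrs["t0_index"] = self.t0_index
            fh.attrs["subject"] = self.subject
            fh.attrs["bad_channels"] = np.array(self.bad_channels, dtype="S")
            for col in self.labels.columns:
                fh.create_dataset(f"labels/{col}", data=self.labels[col].to_numpy(dtype="S" if self.labels[col].dtype == object else None))

    @classmethod
    def load(cls, path, montage: Montage | None = None) -> "EpochSet":
        montage = montage or default_montage()
        with h5py.File(path, "r") as fh:
            data = fh["data"][()]
            cols = {}
            for col in fh["labels"]:
                v = fh[f"labels/{col}"][()]
                cols[col] = [s.decode() for s in v] if v.dtype.kind == "S" else v
            return cls(
                data,
                pd.DataFrame(cols),
                montage,
                sfreq=float(fh.attrs["sfreq"]),
                t0_index=int(fh.attrs["t0_index"]),
                subject=int(fh.attrs["subject"]),
                bad_channels=[s.decode() for s in fh.attrs["bad_channels"]],
            )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def pink_noise(
    n_signals: int, n_times: int, exponent: float, rng: np.random.Generator, chunk: int = 8192
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise rows (FFT-shaped white noise, float32).

    Generated in chunks to keep the float64 FFT temporaries small.
    """
    out = np.empty((n_signals, n_times), dtype=np.float32)
    f = np.fft.rfftfreq(n_times)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    for i in range(0, n_signals, chunk):
        white = rng.standard_normal((min(chunk, n_signals - i), n_times))
        x = np.fft.irfft(np.fft.rfft(white, axis=1) * scale, n=n_times, axis=1)
        x /= np.maximum(x.std(axis=1, keepdims=True), 1e-30)
        out[i : i + len(x)] = x
    return out


def _unit_gain(montage: Montage, source_mm, orientation) -> np.ndarray:
    """Average-referenced gain vector normalized to 1 at its best channel."""
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    g = dipole_potential(np.asarray(source_mm, dtype=float), u, montage)
    return g / np.max(np.abs(g))


def _noise_mixing(montage: Montage, n_sources: int, rng: np.random.Generator) -> np.ndarray:
    """(n_channels, n_sources) gain of random superficial noise dipoles."""
    cols = []
    for _ in range(n_sources):
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pos = montage.sphere_center + d * rng.uniform(0.55, 0.8) * montage.sphere_radius
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        g = dipole_potential(pos, u, montage)
        cols.append(g / np.linalg.norm(g))
    return np.stack(cols, axis=1)


def generate_subject(
    spec: EffectSpec, subject: int, seed: int, montage: Montage | None = None
) -> EpochSet:
    """Generate one subject's full epoch set (all 6 cells), deterministically."""
    montage = montage or default_montage()
    spec.validate(montage)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77, int(subject)]))
    n_ch, n_t = montage.n_channels, spec.n_times
    n_cell = spec.epochs_per_cell
    n_ep = n_cell * len(CELLS)
    t_ms = (np.arange(n_t) - spec.t0_index) / spec.sfreq * 1000.0

    # per-subject multiplicative amplitude jitter, one factor per component
    jit = {
        c.name: float(rng.lognormal(0.0, spec.between_subject_sd))
        for c in [*spec.erp_components, *spec.osc_components]
    }

    data = np.zeros((n_ep, n_ch, n_t), dtype=np.float32)
    rows = []
    ep = 0
    for cond, tt in CELLS:
        cell = (cond, tt)
        # phase-locked template, shared by every epoch of the cell
        template = np.zeros((n_ch, n_t))
        for c in spec.erp_components:
            a = c.amplitude_uv.get(cell, 0.0) * jit[c.name]
            if a == 0.0:
                continue
            wave = a * np.exp(-0.5 * ((t_ms - c.latency_ms) / c.width_ms) ** 2)
            template += np.outer(_unit_gain(montage, c.source_mm, c.orientation), wave)
        block = np.broadcast_to(template, (n_cell, n_ch, n_t)).astype(np.float32).copy()

        # induced oscillations: random phase per trial
        for c in spec.osc_components:
            env = c.base_uv + c.gain_uv.get(cell, 0.0) * jit[c.name] * np.exp(
                -0.5 * ((t_ms - c.center_ms) / c.width_ms) ** 2
            )
            env = np.maximum(env, 0.0)
            if not env.any():
                continue
            gain = _unit_gain(montage, c.source_mm, c.orientation)
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_cell)
            carrier = np.sin(
                2.0 * np.pi * c.freq_hz * t_ms[None, :] / 1000.0 + phases[:, None]
            )
            block += (gain[None, :, None] * (env[None, None, :] * carrier[:, None, :])).astype(
                np.float32
            )
        data[ep : ep + n_cell] = block
        rows += [dict(subject=subject, condition=cond, trial_type=tt, artifact=False)] * n_cell
        ep += n_cell

    labels = pd.DataFrame(rows)

    # background noise
    if spec.noise_sd_uv > 0:
        w_sh = np.float32(np.sqrt(spec.noise_spatial_mix) * spec.noise_sd_uv)
        w_own = np.float32(np.sqrt(1.0 - spec.noise_spatial_mix) * spec.noise_sd_uv)
        data += w_own * pink_noise(n_ep * n_ch, n_t, spec.noise_exponent, rng).reshape(
            n_ep, n_ch, n_t
        )
        mix = _noise_mixing(montage, spec.n_noise_sources, rng).astype(np.float32)
        src = pink_noise(n_ep * spec.n_noise_sources, n_t, spec.noise_exponent, rng).reshape(
            n_ep, spec.n_noise_sources, n_t
        )
        shared = (
            (mix @ src.transpose(1, 0, 2).reshape(spec.n_noise_sources, -1))
            .reshape(n_ch, n_ep, n_t)
            .transpose(1, 0, 2)
        )
        shared /= np.maximum(shared.std(axis=(0, 2), keepdims=True), 1e-30)
        data += w_sh * shared

    out = EpochSet(
        data, labels, montage, sfreq=spec.sfreq, t0_index=spec.t0_index, subject=subject
    )

    # flat bad channels (disconnected electrodes), then artifact epochs
    if spec.n_bad_channels > 0:
        bad_idx = rng.choice(n_ch, size=spec.n_bad_channels, replace=False)
        out.bad_channels = [montage.labels[i] for i in bad_idx]
        drift = 2.0 * pink_noise(len(bad_idx), n_t, 2.0, rng)
        out.data[:, bad_idx, :] = drift[None].astype(np.float32)
    if spec.artifact_rate > 0:
        inject_artifacts(out, spec.artifact_rate, int(rng.integers(2**31)), amp_uv=spec.artifact_amp_uv)
    return out


def iter_subjects(spec: EffectSpec, seed: int, montage: Montage | None = None) -> Iterator[EpochSet]:
    """Yield per-subject EpochSets one at a time (memory-friendly)."""
    montage = montage or default_montage()
    for s in range(spec.n_subjects):
        yield generate_subject(spec, s, seed, montage)


def generate_dataset(spec: EffectSpec, seed: int, montage: Montage | None = None) -> list[EpochSet]:
    """All subjects at once; intended for small test specs."""
    return list(iter_subjects(spec, seed, montage))


def inject_artifacts(epochs: EpochSet, rate: float, seed: int, amp_uv: float = 160.0) -> EpochSet:
    """Add >100 µV excursions to exactly round(rate·n) epochs, flag them, in place."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("artifact rate must be in [0, 1]")
    n = len(epochs.data)
    k = int(round(rate * n))
    if k == 0:
        return epochs
    rng = np.random.default_rng(seed)
    picked = rng.choice(n, size=k, replace=False)
    n_t = epochs.data.shape[2]
    width = int(0.1 * epochs.sfreq)  # 100 ms burst
    window = np.hanning(width)
    for i in picked:
        ch = rng.choice(epochs.data.shape[1], size=int(rng.integers(1, 4)), replace=False)
        start = int(rng.integers(0, n_t - width))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        epochs.data[i, ch[:, None], start + np.arange(width)[None, :]] += (
            sign * amp_uv * window[None, :]
        ).astype(np.float32)
    flagged = epochs.labels["artifact"].to_numpy().copy()
    flagged[picked] = True
    epochs.labels["artifact"] = flagged
    return epochs
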