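"""156-channel spherical EEG montage with named electrode clusters.

The layout is a 10/05-extension template (the naming used by 160-channel
actiCHamp caps) with positions projected onto the analysis sphere
(radius 90 mm, center at MNI (0, 0, 40) mm).  Positions are exactly
left/right mirror-symmetric, which the forward model's symmetry tests rely
on.  The default montage ships with the package as an SFP file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

SPHERE_CENTER_MM = np.array([0.0, 0.0, 40.0])
SPHERE_RADIUS_MM = 90.0

#: Five-electrode cluster sets used by the focused waveform / power analyses.
CLUSTER_SETS: dict[str, tuple[str, ...]] = {
    "frontal": ("AFp1", "AFp2", "AFz", "AFF1h", "AFF2h"),
    "central": ("Cz", "CCP1h", "CCP2h", "FCC1h", "FCC2h"),
    "posterior": ("POz", "PPO1h", "PPO2h", "POO1", "POO2"),
}


@dataclass
class Montage:
    """Electrode labels, 3-D positions (mm, head frame == MNI frame) and clusters."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3) mm
    cluster_sets: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(CLUSTER_SETS))
    sphere_center: np.ndarray = field(default_factory=lambda: SPHERE_CENTER_MM.copy())
    sphere_radius: float = SPHERE_RADIUS_MM

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def cluster_indices(self, name: str) -> np.ndarray:
        if name not in self.cluster_sets:
            raise KeyError(f"unknown cluster set {name!r}")
        return np.array([self.index(lab) for lab in self.cluster_sets[name]])

    # -- geometry ---------------------------------------------------------

    def mirror_permutation(self) -> np.ndarray:
        """Index permutation implementing the left/right label swap.

        Odd electrode numbers are left hemisphere, even numbers right
        (10/05 convention); midline ``...z`` labels map to themselves.
        """
        perm = np.empty(self.n_channels, dtype=int)
        for i, lab in enumerate(self.labels):
            m = re.match(r"^([A-Za-z]+?)(\d+)(h?)$", lab)
            if m is None:  # midline
                perm[i] = i
                continue
            base, num, h = m.groups()
            num = int(num)
            twin = f"{base}{num + 1 if num % 2 else num - 1}{h}"
            perm[i] = self.index(twin)
        return perm

    def adjacency(self, max_edge_mm: float = 50.0) -> np.ndarray:
        """Boolean electrode-adjacency matrix.

        Delaunay triangulation of the positions projected to the plane
        tangent at the vertex (azimuthal equidistant projection), with edges
        longer than ``max_edge_mm`` (3-D chord length) pruned.
        """
        d = self.positions - self.sphere_center
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        theta = np.arccos(np.clip(d[:, 2], -1, 1))
        phi = np.arctan2(d[:, 1], d[:, 0])
        pts = np.c_[theta * np.cos(phi), theta * np.sin(phi)]
        tri = Delaunay(pts)
        n = self.n_channels
        adj = np.zeros((n, n), dtype=bool)
        for simplex in tri.simplices:
            for a in range(3):
                i, j = simplex[a], simplex[(a + 1) % 3]
                if np.linalg.norm(self.positions[i] - self.positions[j]) <= max_edge_mm:
                    adj[i, j] = adj[j, i] = True
        return adj

    # -- IO ---------------------------------------------------------------

    def to_sfp(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lab, p in zip(self.labels, self.positions):
                fh.write(f"{lab}\t{p[0]:.4f}\t{p[1]:.4f}\t{p[2]:.4f}\n")

    @classmethod
    def from_sfp(cls, path: str | Path, **kwargs) -> "Montage":
        labels, pos = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split()
            labels.append(parts[0])
            pos.append([float(x) for x in parts[1:4]])
        return cls(labels, np.array(pos), **kwargs)


def default_montage() -> Montage:
    """The packaged 156-channel spherical template montage."""
    with resources.as_file(resources.files("orfi_eeg.data") / "actichamp156_sphere.sfp") as p:
        mont = Montage.from_sfp(p)
    missing = [lab for labs in CLUSTER_SETS.values() for lab in labs if lab not in mont.labels]
    if missing:
        raise RuntimeError(f"packaged montage is missing cluster electrodes {missing}")
    return mont
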