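"""Scalp electrode geometry for the extended 10-20 (10-10) system.

The built-in montage is the 60-electrode cap used by the BCI Competition III
dataset 3a recordings: a 10-10 subset running from Nz (index 1) through Cz
(index 31) to O2 (index 60).  Positions are constructed on the unit sphere
from the defining rules of the system — electrodes sit at 10 %% increments
along the sagittal midline, the coronal line through the vertex, the 10 %%
circumferential ring, and great-circle arcs between a row's midline electrode
and its ring electrode.  Left/right homologs are exact mirror images by
construction, so symmetry invariants hold to machine precision.

The 2-D layout used for inter-electrode distances (and for topographic maps)
is the azimuthal-equidistant projection about the vertex: planar radius equals
the arc length from Cz, angles are preserved.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "ChannelSplit",
    "load_builtin_montage",
    "project_to_plane",
    "pairwise_distance",
    "builtin_split",
    "BUILTIN_SPLIT_LABELS",
]

#: polar angle of one 10 % step (10 % of the 180-degree nasion-inion arc)
_STEP = math.pi / 10.0
#: polar angle of the circumferential ring (10 % above the equator plane)
_RING_POLAR = 4.0 * _STEP

# ring electrodes on the left hemisphere, ordered front to back; electrode k
# sits at azimuth k * 18 degrees from the front midline along the ring
_RING_LEFT = ["Fp1", "AF7", "F7", "FT7", "T7", "TP7", "P7", "PO7", "O1"]

# midline electrodes: label -> (polar steps from vertex, +1 front / -1 back)
_MIDLINE = {
    "Nz": (5, +1),
    "Fpz": (4, +1),
    "AFz": (3, +1),
    "Fz": (2, +1),
    "FCz": (1, +1),
    "Cz": (0, +1),
    "CPz": (1, -1),
    "Pz": (2, -1),
    "POz": (3, -1),
    "Oz": (4, -1),
}

# interior electrodes on great-circle arcs midline -> left ring electrode:
# label -> (midline anchor, ring anchor, arc fraction t)
_ARC_LEFT = {
    "AF3": ("AFz", "AF7", 0.5),
    "F5": ("Fz", "F7", 0.75),
    "F3": ("Fz", "F7", 0.5),
    "FC5": ("FCz", "FT7", 0.75),
    "FC3": ("FCz", "FT7", 0.5),
    "FC1": ("FCz", "FT7", 0.25),
    "C5": ("Cz", "T7", 0.75),
    "C3": ("Cz", "T7", 0.5),
    "C1": ("Cz", "T7", 0.25),
    "CP5": ("CPz", "TP7", 0.75),
    "CP3": ("CPz", "TP7", 0.5),
    "CP1": ("CPz", "TP7", 0.25),
    "P5": ("Pz", "P7", 0.75),
    "P3": ("Pz", "P7", 0.5),
    "P1": ("Pz", "P7", 0.25),
    "PO3": ("POz", "PO7", 0.5),
}

#: the 60 labels in recording order (index 1 = Nz, 31 = Cz, 60 = O2)
BUILTIN_ORDER = [
    "Nz", "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8", "F7",
    "F5", "F3", "Fz", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1",
    "FCz", "FC2", "FC4", "FC6", "FT8", "T9", "T7", "C5", "C3", "C1",
    "Cz", "C2", "C4", "C6", "T8", "T10", "TP7", "CP5", "CP3", "CP1",
    "CPz", "CP2", "CP4", "CP6", "TP8", "P7", "P5", "P3", "Pz", "P2",
    "P4", "P6", "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
]

#: built-in symmetric low-density subsets (observed electrodes), whole-scalp
#: coverage growing from a 9-electrode frame by filling in F/P then CP rows
BUILTIN_SPLIT_LABELS = {
    9: ["Fp1", "Fp2", "F7", "F8", "C3", "Cz", "C4", "O1", "O2"],
    12: ["Fp1", "Fp2", "F7", "F8", "F3", "F4", "C3", "Cz", "C4", "Pz",
         "O1", "O2"],
    15: ["Fp1", "Fp2", "F7", "F8", "F3", "Fz", "F4", "C3", "Cz", "C4",
         "P3", "Pz", "P4", "O1", "O2"],
    18: ["Fp1", "Fp2", "F7", "F8", "F3", "Fz", "F4", "C3", "Cz", "C4",
         "CP3", "CPz", "CP4", "P3", "Pz", "P4", "O1", "O2"],
}


def _mirror_label(label: str) -> str | None:
    """Homolog across the midline (C3 <-> C4), None for midline labels."""
    head = label.rstrip("0123456789")
    digits = label[len(head):]
    if not digits:
        return None
    n = int(digits)
    partner = n + 1 if n % 2 == 1 else n - 1
    return f"{head}{partner}"


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    omega = math.acos(float(np.clip(np.dot(a, b), -1.0, 1.0)))
    if omega == 0.0:
        return a.copy()
    return (math.sin((1 - t) * omega) * a + math.sin(t * omega) * b) / math.sin(omega)


def _build_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    for label, (steps, sign) in _MIDLINE.items():
        polar = steps * _STEP
        pos[label] = np.array([0.0, sign * math.sin(polar), math.cos(polar)])
    for k, label in enumerate(_RING_LEFT, start=1):
        phi = k * _STEP  # azimuth from the front midline, rotating leftwards
        pos[label] = np.array(
            [-math.sin(_RING_POLAR) * math.sin(phi),
             math.sin(_RING_POLAR) * math.cos(phi),
             math.cos(_RING_POLAR)]
        )
    pos["T9"] = np.array([-1.0, 0.0, 0.0])
    for label, (mid, ring, t) in _ARC_LEFT.items():
        pos[label] = _slerp(pos[mid], pos[ring], t)
    # right hemisphere: exact mirror of the left (x -> -x)
    for label in list(pos):
        partner = _mirror_label(label)
        if partner is not None and partner not in pos:
            p = pos[label]
            pos[partner] = np.array([-p[0], p[1], p[2]])
    return pos


def project_to_plane(positions3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection about the vertex (0, 0, 1).

    Planar radius equals the polar angle (arc length from the vertex on the
    unit sphere); the azimuth is preserved.  Input positions need not be
    exactly unit-norm; they are normalized first.

    Parameters
    ----------
    positions3d : (n, 3) array
        Scalp positions on or near the unit sphere.

    Returns
    -------
    (n, 2) array of planar coordinates (x lateral, y anterior-posterior).
    """
    p = np.atleast_2d(np.asarray(positions3d, dtype=float))
    norms = np.linalg.norm(p, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm position cannot be projected")
    u = p / norms[:, None]
    polar = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    lateral = np.hypot(u[:, 0], u[:, 1])
    out = np.zeros((len(u), 2))
    nz = lateral > 0.0
    out[nz, 0] = polar[nz] * u[nz, 0] / lateral[nz]
    out[nz, 1] = polar[nz] * u[nz, 1] / lateral[nz]
    if np.asarray(positions3d).ndim == 1:
        return out[0]
    return out


@dataclass(frozen=True)
class Montage:
    """Named electrode set with 3-D scalp positions and 2-D planar layout.

    Indices exposed through :meth:`index_of` are 1-based to match the
    recording channel numbering; array attributes are 0-based.
    """

    names: tuple[str, ...]
    positions3d: np.ndarray
    positions2d: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate electrode labels")
        if not (len(self.names) == len(self.positions3d) == len(self.positions2d)):
            raise ValueError("names/positions length mismatch")
        object.__setattr__(
            self, "_index", {n: i + 1 for i, n in enumerate(self.names)}
        )

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, label: str) -> int:
        """1-based channel index of *label*."""
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def position2d(self, label: str) -> np.ndarray:
        return self.positions2d[self.index_of(label) - 1]

    def labels_to_indices(self, labels) -> list[int]:
        return [self.index_of(lb) for lb in labels]

    def homolog(self, label: str) -> str | None:
        """Mirror-image electrode if present in the montage, else None."""
        partner = _mirror_label(label)
        if partner is not None and partner in self._index:
            return partner
        return None

    def to_json(self, path) -> None:
        records = [
            {"label": n, "x": float(p[0]), "y": float(p[1]), "z": float(p[2])}
            for n, p in zip(self.names, self.positions3d)
        ]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            records = json.load(fh)
        names = tuple(r["label"] for r in records)
        p3 = np.array([[r["x"], r["y"], r["z"]] for r in records], dtype=float)
        return cls(names=names, positions3d=p3, positions2d=project_to_plane(p3))


@dataclass(frozen=True)
class ChannelSplit:
    """Partition of montage channels into observed and to-predict targets."""

    observed: tuple[int, ...]  # 1-based montage indices, sorted
    targets: tuple[int, ...]

    def __post_init__(self) -> None:
        obs, tgt = set(self.observed), set(self.targets)
        if not obs:
            raise ValueError("observed set must be nonempty")
        if obs & tgt:
            raise ValueError("observed and target sets overlap")
        object.__setattr__(self, "observed", tuple(sorted(obs)))
        object.__setattr__(self, "targets", tuple(sorted(tgt)))

    @property
    def observed_idx0(self) -> np.ndarray:
        return np.asarray(self.observed, dtype=int) - 1

    @property
    def targets_idx0(self) -> np.ndarray:
        return np.asarray(self.targets, dtype=int) - 1

    @classmethod
    def from_labels(cls, montage: Montage, observed_labels) -> "ChannelSplit":
        obs = sorted(montage.index_of(lb) for lb in observed_labels)
        tgt = sorted(set(range(1, len(montage) + 1)) - set(obs))
        return cls(observed=tuple(obs), targets=tuple(tgt))


def load_builtin_montage() -> Montage:
    """The 60-electrode 10-10 montage in recording order (Nz ... O2)."""
    pos = _build_positions()
    p3 = np.array([pos[label] for label in BUILTIN_ORDER])
    return Montage(
        names=tuple(BUILTIN_ORDER), positions3d=p3, positions2d=project_to_plane(p3)
    )


def pairwise_distance(montage: Montage, i: int, j: int) -> float:
    """Planar Euclidean distance between channels *i* and *j* (1-based)."""
    n = len(montage)
    for k in (i, j):
        if not 1 <= k <= n:
            raise IndexError(f"channel index {k} outside 1..{n}")
    return float(np.linalg.norm(montage.positions2d[i - 1] - montage.positions2d[j - 1]))


def builtin_split(n_observed: int, montage: Montage | None = None) -> ChannelSplit:
    """Built-in symmetric low-density subset with 9, 12, 15 or 18 electrodes.

    Each subset is left-right symmetric and covers frontal, central,
    parietal and occipital regions; the 18-electrode set contains C3, Cz
    and C4.  Targets are the complement within the 60-channel montage.
    """
    if n_observed not in BUILTIN_SPLIT_LABELS:
        raise ValueError(
            f"n_observed must be one of {sorted(BUILTIN_SPLIT_LABELS)}, "
            f"got {n_observed}"
        )
    if montage is None:
        montage = load_builtin_montage()
    return ChannelSplit.from_labels(montage, BUILTIN_SPLIT_LABELS[n_observed])
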