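"""Electrode layouts: 10-20 anchors plus quasi-uniform high-density fillers.

A high-density geodesic net covers the scalp with hundreds of electrodes,
but anatomical bookkeeping is done in terms of the 19 canonical 10-20
positions (Fp1 ... O2).  The layouts built here place those 19 anchors at
their idealized unit-sphere coordinates and fill the remaining electrodes
quasi-uniformly over the upper hemisphere with a Fibonacci lattice.
Electrodes are stored in a seed-shuffled order, mirroring the fact that
hardware channel numbering on a real net is not spatially sorted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TEN_TWENTY_NAMES",
    "ElectrodeLayout",
    "generate_layout",
    "write_sfp",
    "read_sfp",
]

#: Canonical ordering of the 19 10-20 electrode names (frontal to occipital).
TEN_TWENTY_NAMES = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Idealized 10-20 polar coordinates (angle from nose in degrees, positive to
# the right; radius as fraction of the vertex->ear arc, ear level = 0.5).
# These are the classic single-sphere textbook positions.
_POLAR = {
    "Fp1": (-18.0, 0.5), "Fp2": (18.0, 0.5),
    "F7": (-54.0, 0.5), "F3": (-39.0, 0.33), "Fz": (0.0, 0.25),
    "F4": (39.0, 0.33), "F8": (54.0, 0.5),
    "T3": (-90.0, 0.5), "C3": (-90.0, 0.25), "Cz": (0.0, 0.0),
    "C4": (90.0, 0.25), "T4": (90.0, 0.5),
    "T5": (-126.0, 0.5), "P3": (-141.0, 0.33), "Pz": (180.0, 0.25),
    "P4": (141.0, 0.33), "T6": (126.0, 0.5),
    "O1": (-162.0, 0.5), "O2": (162.0, 0.5),
}


class LayoutError(ValueError):
    """Raised for invalid layout configurations."""


def _anchor_xyz() -> np.ndarray:
    """Unit-sphere 3-D coordinates of the 19 anchors (x=right, y=front, z=up)."""
    pts = np.empty((19, 3))
    for i, name in enumerate(TEN_TWENTY_NAMES):
        az_deg, r = _POLAR[name]
        incl = r * np.pi  # inclination from the vertex
        az = np.deg2rad(az_deg)
        pts[i] = (np.sin(incl) * np.sin(az), np.sin(incl) * np.cos(az), np.cos(incl))
    return pts


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the upper unit hemisphere (z >= 0)."""
    if n == 0:
        return np.empty((0, 3))
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    i = np.arange(n)
    z = (i + 0.5) / n  # uniform in z over (0, 1) -> upper hemisphere
    phi = 2.0 * np.pi * i / golden
    rho = np.sqrt(1.0 - z**2)
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


@dataclass
class ElectrodeLayout:
    """Labeled 3-D electrode positions with the 19 10-20 anchors marked.

    Attributes
    ----------
    labels : list of str
        One label per electrode, in storage order.
    coords : ndarray, shape (n, 3)
        Unit-sphere positions (x right, y front, z up).
    anchors : dict
        Maps each of the 19 canonical 10-20 names to its storage index.
    """

    labels: list[str]
    coords: np.ndarray
    anchors: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.labels) != len(self.coords):
            raise LayoutError("labels and coords length mismatch")
        missing = [n for n in TEN_TWENTY_NAMES if n not in self.anchors]
        if missing:
            raise LayoutError(f"missing 10-20 anchors: {missing}")
        if len(set(self.anchors.values())) != len(self.anchors):
            raise LayoutError("anchor indices are not distinct")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def anchor_coords(self) -> np.ndarray:
        """Anchor coordinates in canonical 10-20 order, shape (19, 3)."""
        idx = [self.anchors[n] for n in TEN_TWENTY_NAMES]
        return self.coords[idx]


def generate_layout(n_channels: int = 256, seed: int = 0) -> ElectrodeLayout:
    """Build a high-density layout: 19 anchors + quasi-uniform fillers.

    Parameters
    ----------
    n_channels : int
        Total electrode count, at least 19.
    seed : int
        Controls the storage-order shuffle (and nothing else); layouts are
        bit-identical for equal (n_channels, seed).
    """
    if n_channels < 19:
        raise LayoutError(f"need at least 19 channels, got {n_channels}")
    anchor_pts = _anchor_xyz()
    filler_pts = _fibonacci_hemisphere(n_channels - 19)
    coords = np.vstack([anchor_pts, filler_pts])
    labels = list(TEN_TWENTY_NAMES) + [f"E{i + 1}" for i in range(n_channels - 19)]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_channels)
    coords = coords[perm]
    labels = [labels[i] for i in perm]
    anchors = {name: labels.index(name) for name in TEN_TWENTY_NAMES}
    return ElectrodeLayout(labels=labels, coords=coords, anchors=anchors)


def write_sfp(layout: ElectrodeLayout, path) -> None:
    """Write a whitespace-delimited montage file: ``LABEL x y z`` per line."""
    with open(path, "w") as fh:
        for label, (x, y, z) in zip(layout.labels, layout.coords):
            fh.write(f"{label} {x:.17g} {y:.17g} {z:.17g}\n")


def read_sfp(path) -> ElectrodeLayout:
    """Read a ``LABEL x y z`` montage file written by :func:`write_sfp`."""
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    anchors = {n: labels.index(n) for n in TEN_TWENTY_NAMES if n in labels}
    return ElectrodeLayout(labels=labels, coords=np.asarray(rows), anchors=anchors)
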