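"""Sensor layouts on the unit sphere.

The montage shipped here is a quasi-uniform 128-position arrangement built
with a Fibonacci (golden-angle) spiral over a spherical cap, with the
vertex channel Cz placed exactly at the apex.  Coordinates follow the
head-centred convention x = right, y = anterior, z = up; positions are
unit vectors (multiply by a head radius in metres for physical units).
Vendor geodesic-net geometries are proprietary; a quasi-uniform cap
covering the scalp down to slightly below the equator (cheek/eye
positions) carries the same adjacency and interpolation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Canonical scalp foci used for component topographies, as unit directions.
REGION_DIRECTIONS: dict[str, tuple[float, float, float]] = {
    "vertex": (0.0, 0.0, 1.0),
    "centro-parietal": (0.0, -0.45, 0.893),
    "fronto-central": (0.0, 0.45, 0.893),
    "parieto-occipital": (0.0, -0.85, 0.527),
    "frontal": (0.0, 0.92, 0.392),
    "above-eye": (0.42, 0.86, 0.29),
    "below-eye": (0.46, 0.88, -0.11),
}


@dataclass
class SensorLayout:
    """Named electrode set with 3D unit-sphere positions.

    Parameters
    ----------
    channel_names : list of str
        Unique channel labels, one per position row.
    positions : ndarray, shape (n_channels, 3)
        Unit vectors in head-centred coordinates.
    reference_name : str
        Label of the recording reference channel (default ``"Cz"``).
    """

    channel_names: list[str]
    positions: np.ndarray
    reference_name: str = "Cz"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.channel_names) != self.positions.shape[0]:
            raise ValueError("channel_names and positions disagree in length")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere (|r| = 1 ± 1e-9)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in layout") from None

    def arc_to(self, direction: np.ndarray | str) -> np.ndarray:
        """Great-circle arc (radians) from every channel to a direction.

        ``direction`` may be a 3-vector or one of the named foci in
        :data:`REGION_DIRECTIONS`.
        """
        if isinstance(direction, str):
            direction = np.array(REGION_DIRECTIONS[direction])
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        cosang = np.clip(self.positions @ d, -1.0, 1.0)
        return np.arccos(cosang)

    def subset(self, names: list[str]) -> "SensorLayout":
        idx = [self.index(n) for n in names]
        return SensorLayout(list(names), self.positions[idx].copy(), self.reference_name)

    def to_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "positions": self.positions.tolist(),
            "reference_name": self.reference_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorLayout":
        return cls(list(d["channel_names"]), np.array(d["positions"], dtype=float),
                   d.get("reference_name", "Cz"))


def fibonacci_montage(n_channels: int = 128, z_min: float = -0.35,
                      reference_name: str = "Cz") -> SensorLayout:
    """Quasi-uniform scalp montage on a spherical cap.

    One channel (the reference, default Cz) sits exactly at the apex
    (0, 0, 1); the remaining ``n_channels - 1`` positions follow a
    golden-angle spiral with z descending uniformly from just below the
    apex to ``z_min``.  ``z_min`` below zero extends coverage past the
    equator, mimicking the cheek/periocular positions of high-density
    nets (needed for the virtual EOG derivation).
    """
    if n_channels < 5:
        raise ValueError("need at least 5 channels for a usable montage")
    m = n_channels - 1
    i = np.arange(m)
    # keep the first spiral point clear of the apex channel
    z_max = 1.0 - 1.35 * (1.0 - z_min) / n_channels
    z = z_max - (z_max - z_min) * (i + 0.5) / m
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    positions = np.vstack([[0.0, 0.0, 1.0], pts])
    names = [reference_name] + [f"E{k+1}" for k in range(m)]
    return SensorLayout(names, positions, reference_name)


def eog_pair(layout: SensorLayout) -> tuple[str, str]:
    """Names of the channels closest to the above-eye and below-eye foci.

    The virtual EOG channel is derived by subtracting these two, mirroring
    the clinical practice of recreating eye channels from periocular
    electrodes of a high-density net.
    """
    if layout.n_channels < 2:
        raise ValueError("need at least two channels for an EOG derivation")
    i_above = int(np.argmin(layout.arc_to("above-eye")))
    arc_below = layout.arc_to("below-eye")
    arc_below[i_above] = np.inf  # sparse montages: never reuse the same channel
    i_below = int(np.argmin(arc_below))
    return layout.channel_names[i_above], layout.channel_names[i_below]


def topography(layout: SensorLayout, focus: str | np.ndarray,
               spatial_sd_rad: float = 0.7) -> np.ndarray:
    """Per-channel weights with Gaussian falloff on the sphere, max |w| = 1."""
    arc = layout.arc_to(focus)
    w = np.exp(-0.5 * (arc / spatial_sd_rad) ** 2)
    return w / np.max(np.abs(w))
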