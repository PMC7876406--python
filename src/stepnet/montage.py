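"""Electrode geometry.

The pipeline works on a 64-channel cap. Channel positions are taken from the
standard BioSemi 64 layout and projected onto the unit disc with an
azimuthal-equidistant projection (vertex at the origin, nose toward +y), the
projection conventionally used for scalp topographic maps. All spatial
quantities downstream (topographies, STEP locations, clustering distances)
are expressed in these disc coordinates, so "1.0" means the rim of the head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ChannelGeometry:
    """Named electrodes with 2-D unit-disc positions."""

    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), within the unit disc

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def index(self, name: str) -> int:
        return self.ch_names.index(name)

    def neighbors(self, k: int = 4) -> dict[str, list[str]]:
        """k nearest neighbors of every channel by disc distance."""
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=1)[:, :k]
        return {
            self.ch_names[i]: [self.ch_names[j] for j in order[i]]
            for i in range(self.n_channels)
        }

    def most_anterior(self, k: int = 2) -> list[str]:
        """The k most frontal channels (largest +y); ocular proxy sites."""
        order = np.argsort(-self.positions[:, 1])[:k]
        return [self.ch_names[i] for i in order]


def _azimuthal_equidistant(pos3d: np.ndarray) -> np.ndarray:
    """Project 3-D head-sphere coordinates to the plane.

    Radius in the plane is proportional to the polar angle from the vertex;
    azimuth is preserved (+y = nose). Positions are rescaled so the most
    peripheral electrode sits at radius 0.95, keeping every sensor strictly
    inside the unit disc.
    """
    x, y, z = pos3d.T
    r = np.linalg.norm(pos3d, axis=1)
    theta = np.arccos(np.clip(z / r, -1.0, 1.0))  # polar angle from vertex
    rho = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(rho > 0, x / rho, 0.0)
        uy = np.where(rho > 0, y / rho, 0.0)
    flat = theta[:, None] * np.c_[ux, uy]
    flat *= 0.95 / np.abs(np.linalg.norm(flat, axis=1)).max()
    return flat


def standard_montage(n_channels: int = 64) -> ChannelGeometry:
    """BioSemi 64 cap projected to the unit disc.

    ``n_channels`` < 64 keeps the first channels of the layout (useful for
    small test fixtures).
    """
    import mne

    mont = mne.channels.make_standard_montage("biosemi64")
    ch_pos = mont.get_positions()["ch_pos"]
    names = list(ch_pos)[:n_channels]
    pos3d = np.array([ch_pos[n] for n in names])
    return ChannelGeometry(ch_names=tuple(names), positions=_azimuthal_equidistant(pos3d))


def grid_montage(n_side: int = 4, extent: float = 0.8) -> ChannelGeometry:
    """Regular square grid of synthetic electrodes inside the disc.

    A geometry with exactly controllable positions, used by tests that need
    electrodes to coincide with interpolation-grid nodes.
    """
    axis = np.linspace(-extent, extent, n_side)
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    pos = np.c_[xx.ravel(), yy.ravel()]
    names = tuple(f"G{i:02d}" for i in range(pos.shape[0]))
    return ChannelGeometry(ch_names=names, positions=pos)
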