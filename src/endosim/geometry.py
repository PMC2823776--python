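"""Toroidal geometry helpers.

The world is a ``width x height`` rectangle whose edges wrap horizontally and
vertically; all distances are minimum-image.  Positions are continuous, in
patch units.  Headings follow the compass convention of grid-world
simulators: 0 deg = north (+y), 90 deg = east (+x), increasing clockwise.
"""

from __future__ import annotations

import numpy as np


def wrap(xy: np.ndarray, width: float, height: float) -> np.ndarray:
    """Map coordinates into [0, width) x [0, height).

    Tiny negative values can round to exactly ``width`` under the float
    modulo; those are folded back to 0 to keep the half-open interval.
    """
    out = np.asarray(xy, dtype=float).copy()
    out[..., 0] %= width
    out[..., 1] %= height
    out[..., 0] = np.where(out[..., 0] >= width, 0.0, out[..., 0])
    out[..., 1] = np.where(out[..., 1] >= height, 0.0, out[..., 1])
    return out


def torus_delta(a: np.ndarray, b: np.ndarray, width: float,
                height: float) -> np.ndarray:
    """Minimum-image displacement from ``a`` to ``b`` (broadcasting)."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d = d.copy()
    d[..., 0] -= np.round(d[..., 0] / width) * width
    d[..., 1] -= np.round(d[..., 1] / height) * height
    return d


def torus_dist(a: np.ndarray, b: np.ndarray, width: float,
               height: float) -> np.ndarray:
    """Minimum-image Euclidean distance (broadcasting)."""
    d = torus_delta(a, b, width, height)
    return np.sqrt(np.sum(d * d, axis=-1))


def heading_to_unit(heading_deg: np.ndarray) -> np.ndarray:
    """Unit displacement for a compass heading (0=N, 90=E, clockwise)."""
    rad = np.deg2rad(np.asarray(heading_deg, dtype=float))
    return np.stack([np.sin(rad), np.cos(rad)], axis=-1)


def angle_to_sector(dx: np.ndarray, dy: np.ndarray, n_sectors: int = 8
                    ) -> np.ndarray:
    """Index of the compass sector containing displacement (dx, dy).

    Sector 0 is centred on north, sector indices increase clockwise
    (0=N, 1=NE, 2=E, ...).
    """
    ang = np.rad2deg(np.arctan2(dx, dy)) % 360.0  # compass angle
    width = 360.0 / n_sectors
    return (np.floor((ang + width / 2.0) / width) % n_sectors).astype(int)
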