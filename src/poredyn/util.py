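"""Periodic-boundary helpers: minimum image, wrapping, unwrapping."""

from __future__ import annotations

import numpy as np


def minimum_image(dx: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Nearest-periodic-copy displacement for an orthorhombic box."""
    return dx - box * np.round(dx / box)


def wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary box [0, L) per axis."""
    return np.mod(coords, box)


def unwrap(traj_coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Remove periodic jumps along a trajectory by per-step minimum image.

    Requires every per-step displacement to be smaller than half the box on
    each axis (validated); otherwise the minimum-image step is ambiguous.

    Parameters
    ----------
    traj_coords : (n_frames, n_atoms, 3) wrapped coordinates, nm
    box : (n_frames, 3) box lengths, nm
    """
    steps = np.diff(traj_coords, axis=0)
    b = box[1:, None, :]
    mi = minimum_image(steps, b)
    if np.any(np.abs(mi) >= b / 2 - 1e-12):
        raise ValueError("per-step displacement >= box/2: unwrapping ambiguous")
    out = np.empty_like(traj_coords)
    out[0] = traj_coords[0]
    np.cumsum(mi, axis=0, out=mi)
    out[1:] = traj_coords[0] + mi
    return out
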