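"""Water classification inside the pore, filling curves, occupancy statistics.

A water is "inside" by its oxygen position only — a single unambiguous
site, consistent with the density maps.  Positions are wrapped into the
primary box before classification; no unwrapping is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AtomGroup, Trajectory
from .geometry import PoreRegion
from .util import wrap


@dataclass
class OccupancySeries:
    """Per-frame inside count plus cumulative distinct-entrant count."""

    times: np.ndarray  # ps
    counts: np.ndarray  # inside count per frame
    cumulative_entrants: np.ndarray  # distinct molecules ever inside, per frame
    region: PoreRegion


def classify_inside(frame_coords: np.ndarray, region: PoreRegion, waters: AtomGroup, box: np.ndarray | None = None) -> np.ndarray:
    """Boolean inside-mask per water (oxygen site), in group order.

    ``z in [z_lo, z_hi)`` and radial distance strictly below the bound; a
    particle exactly on the upper face or the radial wall is outside.
    """
    pos = frame_coords[waters.indices]
    if box is not None:
        pos = wrap(pos, np.asarray(box))
    return region.contains(pos)


def filling_curve(traj: Trajectory, region: PoreRegion, waters: AtomGroup) -> OccupancySeries:
    """Per-frame inside count and the running number of distinct entrants."""
    counts = np.zeros(traj.n_frames, dtype=int)
    cumulative = np.zeros(traj.n_frames, dtype=int)
    ever = np.zeros(len(waters), dtype=bool)
    for f in range(traj.n_frames):
        mask = classify_inside(traj.coords[f], region, waters, box=traj.box[f])
        counts[f] = int(mask.sum())
        ever |= mask
        cumulative[f] = int(ever.sum())
    return OccupancySeries(times=traj.times.copy(), counts=counts, cumulative_entrants=cumulative, region=region)


def mean_occupancy(
    series: OccupancySeries | list[OccupancySeries],
    t_start: float | None = None,
) -> tuple[float, float]:
    """Mean and sd of the inside count over frames with ``time >= t_start``.

    ``t_start`` defaults to 20% of the span (equilibrium average).  Given a
    list of replicate series the result is the mean of replicate means with
    the sd taken across replicates.
    """
    if isinstance(series, OccupancySeries):
        t0 = series.times[0] + 0.2 * (series.times[-1] - series.times[0]) if t_start is None else t_start
        sel = series.times >= t0
        if not sel.any():
            raise ValueError("no frames at or after t_start")
        vals = series.counts[sel]
        return float(vals.mean()), float(vals.std(ddof=0))
    if not series:
        raise ValueError("empty replicate list")
    means = np.array([mean_occupancy(s, t_start)[0] for s in series])
    sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    return float(means.mean()), sd
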