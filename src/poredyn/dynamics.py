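"""Windowed displacement statistics, MSD-based diffusion, survival curves.

Diffusion follows the Einstein relation MSD(t) = 2 d D t with d the
dimensionality of the motion considered (1 for axial, 3 for full 3-D); the
self-diffusion coefficient is the least-squares slope of the
origin-averaged MSD over a chosen lag window.  Coordinates are unwrapped by
accumulated per-step minimum image before any displacement is computed.

The survival probability P(t) is the fraction of molecules inside the pore
region at a time origin that remain *continuously* inside through t0 + t,
averaged over origins — the strict reading of "remaining encapsulated".  An
intermittent variant (inside at t0 and t0 + t, excursions allowed) is
exposed as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confinement import classify_inside
from .core import AtomGroup, Trajectory
from .geometry import PoreRegion
from .util import unwrap

#: 1 nm^2/ps expressed in m^2/s
M2_S_PER_NM2_PS = 1e-6


@dataclass
class DisplacementDistribution:
    """Squared net displacements pooled over qualifying window passes."""

    window_length: float  # ps
    displacements: np.ndarray  # nm^2, one value per (molecule, window) pass

    @property
    def n_samples(self) -> int:
        return len(self.displacements)


@dataclass
class SurvivalCurve:
    lags: np.ndarray  # ps
    probability: np.ndarray  # [0, 1], P(0) = 1


def _inside_matrix(traj: Trajectory, region: PoreRegion | None, waters: AtomGroup) -> np.ndarray:
    """(n_frames, n_waters) boolean inside-mask; all-True when region is None."""
    if region is None:
        return np.ones((traj.n_frames, len(waters)), dtype=bool)
    out = np.empty((traj.n_frames, len(waters)), dtype=bool)
    for f in range(traj.n_frames):
        out[f] = classify_inside(traj.coords[f], region, waters, box=traj.box[f])
    return out


def windowed_displacements(
    traj: Trajectory,
    region: PoreRegion | None,
    waters: AtomGroup,
    window_length: float = 100.0,
    n_windows: int = 160,
) -> DisplacementDistribution:
    """Net squared displacement per molecule over fixed-length time windows.

    ``n_windows`` start frames are evenly spaced (possibly overlapping)
    over the span that leaves room for a full window.  A molecule
    contributes to a window only if it is inside the region at *every*
    frame of that window; its contribution is the squared net (unwrapped)
    displacement between the window's first and last frame.
    """
    w = int(round(window_length / traj.dt))
    if w < 1 or w > traj.n_frames - 1:
        raise ValueError("window does not fit in trajectory")
    starts = np.unique(np.linspace(0, traj.n_frames - 1 - w, n_windows).round().astype(int))
    unwrapped = unwrap(traj.coords[:, waters.indices], traj.box)
    inside = _inside_matrix(traj, region, waters)
    pooled: list[np.ndarray] = []
    for s in starts:
        qual = inside[s : s + w + 1].all(axis=0)
        if not qual.any():
            continue
        d = unwrapped[s + w, qual] - unwrapped[s, qual]
        pooled.append((d * d).sum(axis=1))
    if not pooled:
        raise ValueError("no molecule stayed inside for a whole window")
    return DisplacementDistribution(window_length=window_length, displacements=np.concatenate(pooled))


def displacement_histogram(
    dd: DisplacementDistribution,
    bins: int | np.ndarray = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability histogram (edges, probabilities summing to 1)."""
    if dd.n_samples == 0:
        raise ValueError("no displacements to histogram")
    counts, edges = np.histogram(dd.displacements, bins=bins)
    return edges, counts / counts.sum()


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Origin-averaged MSD per lag for (n_frames, n_atoms, dims) positions.

    Standard FFT decomposition MSD(m) = S1(m) - 2 S2(m), with S2 the
    positional autocorrelation; O(N log N) per atom instead of O(N^2).
    """
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    s2 = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:n].real
    s2 = s2.sum(axis=2)  # over dims -> (n_lags, n_atoms)
    norm = (n - np.arange(n))[:, None]
    s2 /= norm
    d = (x * x).sum(axis=2)  # (n_frames, n_atoms)
    q = 2.0 * d.sum(axis=0)
    s1 = np.empty_like(s2)
    for m in range(n):
        if m > 0:
            q -= d[m - 1] + d[n - m]
        s1[m] = q / (n - m)
    return (s1 - 2.0 * s2).mean(axis=1)  # average over atoms


def estimate_diffusion(
    traj: Trajectory,
    group: AtomGroup,
    mode: str = "full_3d",
    fit_window: tuple[float, float] = (50.0, 500.0),
) -> tuple[float, float]:
    """Self-diffusion coefficient in m²/s from the MSD slope, with stderr.

    The MSD is averaged over all time origins (FFT method) and atoms of the
    group; D = slope / (2 d) with d = 3 (``full_3d``) or 1 (``axial_1d``,
    z-component only, the relevant mode for pore-confined motion).
    """
    if mode not in ("full_3d", "axial_1d"):
        raise ValueError("mode must be 'full_3d' or 'axial_1d'")
    x = unwrap(traj.coords[:, group.indices], traj.box)
    if mode == "axial_1d":
        x = x[:, :, 2:3]
    dims = x.shape[2]
    msd = _msd_fft(x)
    lags = traj.dt * np.arange(len(msd))
    sel = (lags >= fit_window[0]) & (lags <= fit_window[1]) & (lags > 0)
    if sel.sum() <= 2:
        raise ValueError("fit window covers <= 2 lag points")
    A = np.stack([lags[sel], np.ones(sel.sum())], axis=1)
    coef, res, *_ = np.linalg.lstsq(A, msd[sel], rcond=None)
    slope = coef[0]
    dof = sel.sum() - 2
    if len(res) and dof > 0:
        s2 = res[0] / dof
        cov = s2 * np.linalg.inv(A.T @ A)[0, 0]
        slope_err = float(np.sqrt(cov))
    else:
        slope_err = 0.0
    d_est = slope / (2.0 * dims) * M2_S_PER_NM2_PS
    return float(d_est), slope_err / (2.0 * dims) * M2_S_PER_NM2_PS


def survival_probability(
    traj: Trajectory,
    region: PoreRegion,
    waters: AtomGroup,
    max_lag: float | None = None,
    continuous: bool = True,
) -> SurvivalCurve:
    """Survival probability of region residence versus lag time.

    P(t) = < N_cont(t0, t0 + t) / N(t0) > over origins t0 with N(t0) > 0,
    where N_cont counts molecules inside at t0 and (with ``continuous``,
    the default) at every intermediate frame through t0 + t.

    The origin set is fixed across lags (every t0 that leaves room for the
    *maximum* lag), which makes the continuous curve non-increasing by
    construction.  ``max_lag`` defaults to half the trajectory span.
    """
    inside = _inside_matrix(traj, region, waters)
    n_frames = len(inside)
    if not inside.any():
        raise ValueError("region never occupied")
    dt = traj.dt if n_frames > 1 else 1.0
    if max_lag is None:
        max_lag_frames = (n_frames - 1) // 2
    else:
        max_lag_frames = min(n_frames - 1, int(round(max_lag / dt)))
    t0_max = n_frames - max_lag_frames  # origins 0 .. t0_max-1, fixed for all lags
    n0 = inside[:t0_max].sum(axis=1)
    valid = n0 > 0
    if not valid.any():
        raise ValueError("region never occupied within the origin span")
    # run length of consecutive inside frames starting at each t0
    runlen = np.zeros((n_frames, inside.shape[1]), dtype=int)
    runlen[-1] = inside[-1]
    for t in range(n_frames - 2, -1, -1):
        runlen[t] = np.where(inside[t], runlen[t + 1] + 1, 0)
    prob = np.empty(max_lag_frames + 1)
    for lag in range(max_lag_frames + 1):
        if continuous:
            surv = (runlen[:t0_max] >= lag + 1).sum(axis=1)
        else:
            surv = (inside[:t0_max] & inside[lag : lag + t0_max]).sum(axis=1)
        prob[lag] = float((surv[valid] / n0[valid]).mean())
    return SurvivalCurve(lags=dt * np.arange(max_lag_frames + 1), probability=prob)
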