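"""Ion transport analysis: z-traces, entrants, RDF, coordination, selectivity.

The workflow mirrors how channel selectivity is characterised from MD: per-
ion z-trajectories and inside flags, the number of distinct ions that ever
enter the pore, a cation–water-oxygen radial distribution function whose
first minimum defines the first coordination shell, and coordination
numbers of inside ions split by oxygen source (water versus peptide
carbonyl).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import N_A
from scipy.spatial import cKDTree

from .confinement import classify_inside
from .core import AtomGroup, Trajectory
from .geometry import PoreRegion
from .util import wrap


@dataclass
class IonTrace:
    ion_id: int
    species: str  # "cation" or "anion"
    z: np.ndarray  # nm per frame
    inside: np.ndarray  # bool per frame


@dataclass
class RDFCurve:
    r: np.ndarray  # bin centres, nm
    g: np.ndarray  # dimensionless
    reference: str = ""
    target: str = ""


@dataclass
class CoordinationResult:
    """Oxygen coordination of inside ions, split by oxygen source."""

    counts_by_source: dict[str, np.ndarray]  # per (ion, frame) observation
    mean_by_source: dict[str, float]
    mean_total: float
    n_observations: int


@dataclass
class SelectivityReport:
    cation_entrants: int
    anion_entrants: int
    mean_occupancy_cation: float
    mean_occupancy_anion: float
    ratio: float  # inf when anions never enter
    infinite: bool


def ion_z_traces(traj: Trajectory, ions: AtomGroup, region: PoreRegion) -> list[IonTrace]:
    """Per-ion z series and inside flags over the trajectory."""
    inside = np.empty((traj.n_frames, len(ions)), dtype=bool)
    for f in range(traj.n_frames):
        inside[f] = classify_inside(traj.coords[f], region, ions, box=traj.box[f])
    z = traj.coords[:, ions.indices, 2]
    roles = ions.topology.roles[ions.indices]
    return [
        IonTrace(ion_id=int(ions.indices[i]), species=str(roles[i]), z=z[:, i].copy(), inside=inside[:, i].copy())
        for i in range(len(ions))
    ]


def count_entrants(traces: list[IonTrace], species: str | None = None) -> int:
    """Distinct ions (optionally of one species) with at least one inside frame."""
    if not traces:
        raise ValueError("no ion traces")
    return sum(1 for t in traces if (species is None or t.species == species) and t.inside.any())


def rdf(
    traj: Trajectory,
    reference: AtomGroup,
    target: AtomGroup,
    r_max: float = 1.2,
    bin_size: float = 0.002,
) -> RDFCurve:
    """Radial distribution function g(r) between two groups.

    Pair distances use the minimum image (periodic k-d tree); the histogram
    is normalized by the ideal-gas expectation N_ref * rho_target *
    V_shell per frame, with self-pairs excluded for overlapping groups.
    """
    if len(reference) == 0 or len(target) == 0:
        raise ValueError("reference and target must be nonempty")
    if r_max >= traj.box.min() / 2:
        raise ValueError("r_max must be below half the smallest box length")
    edges = np.arange(0.0, r_max + bin_size, bin_size)
    shared = np.intersect1d(reference.indices, target.indices)
    cumulative = np.zeros(len(edges))
    ideal = 0.0
    for f in range(traj.n_frames):
        box = traj.box[f]
        ref_pos = wrap(traj.coords[f, reference.indices], box)
        tgt_pos = wrap(traj.coords[f, target.indices], box)
        tree_r = cKDTree(ref_pos, boxsize=box)
        tree_t = cKDTree(tgt_pos, boxsize=box)
        cum = tree_r.count_neighbors(tree_t, edges).astype(float)
        cum -= len(shared)  # self pairs sit at r = 0 in every cumulative count
        cumulative += cum
        volume = float(np.prod(box))
        n_pairs = len(reference) * len(target) - len(shared)
        ideal += n_pairs / volume
    shell_counts = np.diff(cumulative)
    shell_vol = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    g = shell_counts / (ideal * shell_vol)
    return RDFCurve(r=(edges[:-1] + edges[1:]) / 2, g=g)


def first_minimum(curve: RDFCurve, smoothing_window: int = 5, min_prominence: float = 0.05) -> float:
    """First local minimum of g(r) after its first maximum (shell cutoff).

    The curve is smoothed with a centred moving average of
    ``smoothing_window`` bins (1 = raw); extrema must have a prominence of
    at least ``min_prominence`` times the curve's range, so noise wiggles
    are not mistaken for the coordination-shell structure.
    """
    from scipy.signal import find_peaks

    g = curve.g
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        g = np.convolve(g, kernel, mode="same")
    prominence = min_prominence * (g.max() - g.min())
    maxima, _ = find_peaks(g, prominence=prominence)
    if not len(maxima):
        raise ValueError("no first minimum found (monotone or featureless curve)")
    tail = g[maxima[0]:]
    minima, _ = find_peaks(-tail, prominence=prominence)
    if not len(minima):
        raise ValueError("no first minimum found (monotone or featureless curve)")
    return float(curve.r[maxima[0] + minima[0]])


def coordination_numbers(
    traj: Trajectory,
    ions: AtomGroup,
    region: PoreRegion | None,
    oxygens_by_source: dict[str, AtomGroup],
    cutoff: float,
) -> CoordinationResult:
    """Oxygen counts within ``cutoff`` of each inside ion, split by source.

    ``oxygens_by_source`` maps a label (e.g. ``water``, ``carbonyl``) to an
    oxygen group; each (inside ion, frame) pair contributes one observation
    per source.  With ``region=None`` every ion counts in every frame.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    per_source: dict[str, list[int]] = {s: [] for s in oxygens_by_source}
    n_obs = 0
    for f in range(traj.n_frames):
        box = traj.box[f]
        if region is not None:
            mask = classify_inside(traj.coords[f], region, ions, box=box)
        else:
            mask = np.ones(len(ions), dtype=bool)
        if not mask.any():
            continue
        ion_pos = wrap(traj.coords[f, ions.indices[mask]], box)
        n_obs += int(mask.sum())
        for source, group in oxygens_by_source.items():
            ox_pos = wrap(traj.coords[f, group.indices], box)
            tree = cKDTree(ox_pos, boxsize=box)
            counts = tree.query_ball_point(ion_pos, r=cutoff, return_length=True)
            per_source[source].extend(int(c) for c in counts)
    if n_obs == 0:
        raise ValueError("no ion was ever inside the region")
    arrays = {s: np.asarray(v) for s, v in per_source.items()}
    mean_by_source = {s: float(a.mean()) for s, a in arrays.items()}
    total = np.sum(list(arrays.values()), axis=0)
    return CoordinationResult(
        counts_by_source=arrays,
        mean_by_source=mean_by_source,
        mean_total=float(np.asarray(total).mean()),
        n_observations=n_obs,
    )


def selectivity_summary(
    cation_traces: list[IonTrace],
    anion_traces: list[IonTrace],
) -> SelectivityReport:
    """Entrant counts, mean inside occupancy per species and their ratio."""
    cat = count_entrants(cation_traces) if cation_traces else 0
    ani = count_entrants(anion_traces) if anion_traces else 0
    occ_c = float(np.sum([t.inside for t in cation_traces], axis=0).mean()) if cation_traces else 0.0
    occ_a = float(np.sum([t.inside for t in anion_traces], axis=0).mean()) if anion_traces else 0.0
    infinite = ani == 0 and cat > 0
    ratio = float("inf") if infinite else (cat / ani if ani else 0.0)
    return SelectivityReport(
        cation_entrants=cat,
        anion_entrants=ani,
        mean_occupancy_cation=occ_c,
        mean_occupancy_anion=occ_a,
        ratio=ratio,
        infinite=infinite,
    )


def ion_pairs_for_molarity(concentration_molar: float, box_nm: tuple[float, float, float]) -> int:
    """Ion pairs for a salt concentration in an orthorhombic box.

    round(c * V * N_A) with V in litres (1 nm^3 = 1e-24 L); e.g. 0.15 M in
    a 12.7 x 13.4 x 8.5 nm^3 box gives 131 pairs.
    """
    if concentration_molar < 0 or any(b <= 0 for b in box_nm):
        raise ValueError("concentration must be >= 0 and box lengths > 0")
    volume_litres = float(np.prod(box_nm)) * 1e-24
    return int(round(concentration_molar * volume_litres * N_A))
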