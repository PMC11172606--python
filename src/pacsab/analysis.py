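"""Trajectory analysis: every results-page quantity of the simulation
workflow — minimum intermolecular distance, intra/intermolecular contact
maps, radius-of-gyration series and distribution, RMSD evolution,
frame-vs-frame 2D-RMSD, association/dissociation events — plus the
diffusion-limited collision-time estimator.

All quantities are defined on whole-molecule (re-wrapped) frame
coordinates; intermolecular distances use the minimum-image convention.
Analyses accept partial trajectories, so they can run on-the-fly while a
simulation is still producing frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ModelError
from .io_formats import Trajectory


@dataclass
class DistanceTrace:
    """Per-frame minimum intermolecular particle distance (A)."""

    times: np.ndarray  # ps
    values: np.ndarray  # A

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ContactMap:
    """Residue x residue contact counts accumulated over a frame range."""

    counts: np.ndarray  # (n_res, n_res) nonnegative ints
    mode: str  # "intra" | "inter"
    cutoff: float
    frame_range: tuple


@dataclass
class RgHistogram:
    edges: np.ndarray
    density: np.ndarray  # integrates to 1


@dataclass
class AssociationEvents:
    """Bound intervals from a hysteresis threshold pair on the minimum
    intermolecular distance trace."""

    intervals: list  # (t_on, t_off or None)
    n_associations: int
    n_dissociations: int
    bound_fraction: float


def _mi(d, L):
    return d - L * np.floor(d / L + 0.5)


def min_intermolecular_distance(coords, mol_index, L, kinds=None,
                                heavy_only: bool = False) -> float:
    """Minimum over all inter-molecule particle pairs of the minimum-image
    distance (A)."""
    mol = np.asarray(mol_index)
    a = np.asarray(coords)[mol == 0]
    b = np.asarray(coords)[mol == 1]
    if heavy_only and kinds is not None:
        a = np.asarray(coords)[(mol == 0) & (np.asarray(kinds) != 1)]
        b = np.asarray(coords)[(mol == 1) & (np.asarray(kinds) != 1)]
    if len(a) == 0 or len(b) == 0:
        raise ModelError("two molecules required for intermolecular distance")
    d = _mi(a[:, None, :] - b[None, :, :], L)
    return float(np.sqrt((d ** 2).sum(axis=2)).min())


def distance_trace(traj: Trajectory, heavy_only: bool = False) -> DistanceTrace:
    vals = np.array([
        min_intermolecular_distance(traj.coords[f], traj.mol_index, traj.box,
                                    kinds=traj.kinds, heavy_only=heavy_only)
        for f in range(traj.n_frames)])
    return DistanceTrace(times=traj.times.copy(), values=vals)


def contact_map(traj: Trajectory, mode: str = "inter", cutoff: float = 6.5,
                frame_range: tuple | None = None) -> ContactMap:
    """Accumulated residue-residue contacts.

    A residue pair counts once per frame when any inter-residue particle
    pair is closer than ``cutoff`` (minimum image). Intramolecular maps
    require |i-j| >= 3 and sum both molecules; intermolecular maps of the
    homodimer are symmetrised. Accumulation is additive over disjoint
    frame ranges."""
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    lo, hi = (0, traj.n_frames) if frame_range is None else frame_range
    mol = np.asarray(traj.mol_index)
    res = np.asarray(traj.res_index)
    nres = int(res[mol == 0].max()) + 1  # residues per chain
    resseq = np.where(mol == 1, res - nres, res)
    counts = np.zeros((nres, nres), dtype=np.int64)
    for f in range(lo, hi):
        pos = traj.coords[f]
        d = _mi(pos[:, None, :] - pos[None, :, :], traj.box)
        close = (d ** 2).sum(axis=2) < cutoff * cutoff
        ii, jj = np.nonzero(np.triu(close, k=1))
        seen = np.zeros((nres, nres), dtype=bool)
        if mode == "inter":
            inter = mol[ii] != mol[jj]
            for a, b in zip(ii[inter], jj[inter]):
                ra, rb = int(resseq[a]), int(resseq[b])
                seen[ra, rb] = True
                seen[rb, ra] = True
        else:
            intra = mol[ii] == mol[jj]
            for a, b in zip(ii[intra], jj[intra]):
                ra, rb = int(resseq[a]), int(resseq[b])
                if abs(ra - rb) < 3:
                    continue
                seen[ra, rb] = True
                seen[rb, ra] = True
        counts += seen
    return ContactMap(counts=counts, mode=mode, cutoff=cutoff, frame_range=(lo, hi))


def radius_of_gyration(coords, masses) -> float:
    """Mass-weighted radius of gyration (A)."""
    coords = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_series(traj: Trajectory) -> np.ndarray:
    """Per-frame, per-molecule Rg; shape (n_frames, n_molecules)."""
    mol = np.asarray(traj.mol_index)
    nmol = int(mol.max()) + 1
    out = np.empty((traj.n_frames, nmol))
    for m in range(nmol):
        sel = mol == m
        for f in range(traj.n_frames):
            out[f, m] = radius_of_gyration(traj.coords[f, sel], traj.masses[sel])
    return out


def rg_distribution(traj: Trajectory, bin_width: float = 1.0) -> RgHistogram:
    """Normalised Rg histogram pooled over molecules and frames (1 A bins
    from 0 to 1.5x the maximum observed Rg)."""
    rg = rg_series(traj).ravel()
    top = 1.5 * rg.max()
    edges = np.arange(0.0, top + bin_width, bin_width)
    density, edges = np.histogram(rg, bins=edges, density=True)
    return RgHistogram(edges=edges, density=density)


def rmsd(frame, reference, weights=None) -> float:
    """Optimal-superposition (Kabsch) RMSD between two coordinate sets."""
    p = np.asarray(frame, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.shape[0] < 3:
        raise ModelError("RMSD needs two equal selections of >= 3 particles")
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    pc = p - (w[:, None] * p).sum(axis=0) / w.sum()
    qc = q - (w[:, None] * q).sum(axis=0) / w.sum()
    _, rssd = Rotation.align_vectors(pc, qc, weights=w)
    return float(rssd / np.sqrt(w.sum()))


def _selection(traj: Trajectory, mol: int, selection: str) -> np.ndarray:
    sel = np.asarray(traj.mol_index) == mol
    if selection == "backbone":
        sel &= np.asarray(traj.kinds) != 5
    return np.nonzero(sel)[0]


def rmsd_series(traj: Trajectory, selection: str = "backbone") -> np.ndarray:
    """Per-frame, per-molecule RMSD vs the first frame; shape
    (n_frames, n_molecules). Backbone particles only by default, matching
    the backbone-resolution trajectory export."""
    nmol = int(np.asarray(traj.mol_index).max()) + 1
    out = np.empty((traj.n_frames, nmol))
    for m in range(nmol):
        idx = _selection(traj, m, selection)
        ref = traj.coords[0, idx]
        for f in range(traj.n_frames):
            out[f, m] = rmsd(traj.coords[f, idx], ref)
    return out


def rmsd_2d(traj: Trajectory, stride: int = 1, mol: int = 0,
            selection: str = "backbone") -> np.ndarray:
    """Frame x frame RMSD matrix over strided frames (structural-cluster
    view). Symmetric with a zero diagonal; the triangle inequality may be
    violated because each pair is superposed independently."""
    idx = _selection(traj, mol, selection)
    frames = traj.coords[::stride, idx]
    nf = len(frames)
    m = np.zeros((nf, nf))
    for i in range(nf):
        for j in range(i + 1, nf):
            m[i, j] = m[j, i] = rmsd(frames[i], frames[j])
    return m


def association_events(trace: DistanceTrace, d_on: float = 5.0,
                       d_off: float = 8.0) -> AssociationEvents:
    """Hysteresis state machine on the minimum-distance trace: the pair
    binds when the trace drops below ``d_on`` and unbinds when it rises
    above ``d_off``; excursions between the thresholds change nothing."""
    if d_on >= d_off:
        raise ValueError("d_on must be below d_off")
    bound = False
    intervals = []
    t_on = None
    n_on = n_off = 0
    bound_samples = 0
    for t, d in zip(trace.times, trace.values):
        if not bound and d < d_on:
            bound = True
            t_on = t
            n_on += 1
        elif bound and d > d_off:
            bound = False
            intervals.append((t_on, t))
            n_off += 1
        if bound:
            bound_samples += 1
    if bound:
        intervals.append((t_on, None))
    return AssociationEvents(
        intervals=intervals,
        n_associations=n_on,
        n_dissociations=n_off,
        bound_fraction=bound_samples / max(len(trace), 1),
    )


def collision_time(encounter_rate_per_s_per_M: float = 1e10,
                   concentration_M: float = 5e-4) -> float:
    """Mean diffusion-limited encounter time tau = 1/(k C), in ns.

    With the water-typical encounter frequency k ~ 1e10 /s/M, a 0.5 mM
    solution collides about every 200 ns."""
    if encounter_rate_per_s_per_M <= 0 or concentration_M <= 0:
        raise ValueError("rate and concentration must be positive")
    return 1.0 / (encounter_rate_per_s_per_M * concentration_M) * 1e9


def hbond_occupancy(traj: Trajectory, sep: int = 4, r_cut: float = 2.6,
                    angle_cut_deg: float = 120.0) -> np.ndarray:
    """Per-frame fraction of (i, i+sep) backbone hydrogen bonds present
    (helical O(i)...H(i+sep) geometry: r_HO < r_cut and N-H...O angle
    above ``angle_cut_deg``)."""
    kinds = np.asarray(traj.kinds)
    res = np.asarray(traj.res_index)
    mol = np.asarray(traj.mol_index)
    atom = {}
    for i in range(traj.n_particles):
        atom[(int(res[i]), int(kinds[i]))] = i
    pairs = []  # (O_i, N_j, H_j)
    for r in np.unique(res):
        if (r, 4) not in atom or (r + sep, 0) not in atom or (r + sep, 1) not in atom:
            continue
        if mol[atom[(r, 4)]] != mol[atom[(r + sep, 0)]]:
            continue
        pairs.append((atom[(r, 4)], atom[(r + sep, 0)], atom[(r + sep, 1)]))
    if not pairs:
        return np.zeros(traj.n_frames)
    pairs = np.asarray(pairs)
    occ = np.empty(traj.n_frames)
    cos_cut = np.cos(np.deg2rad(angle_cut_deg))
    for f in range(traj.n_frames):
        pos = traj.coords[f]
        o, n, h = pos[pairs[:, 0]], pos[pairs[:, 1]], pos[pairs[:, 2]]
        v = o - h
        r_ho = np.linalg.norm(v, axis=1)
        u = n - h
        cosang = (u * v).sum(axis=1) / (np.linalg.norm(u, axis=1) * r_ho)
        occ[f] = np.mean((r_ho < r_cut) & (cosang < cos_cut))
    return occ


@dataclass
class AnalysisBundle:
    """Everything the results page shows, computed in one pass."""

    distance: DistanceTrace
    contacts_intra: ContactMap
    contacts_inter: ContactMap | None
    rg: np.ndarray  # (n_frames, n_mol)
    rg_hist: RgHistogram
    rmsd: np.ndarray  # (n_frames, n_mol)
    rmsd2d: np.ndarray
    events: AssociationEvents | None
    times: np.ndarray = field(default=None)


def analyze_all(traj: Trajectory, contact_cutoff: float = 6.5,
                rmsd2d_stride: int = 10, d_on: float = 5.0,
                d_off: float = 8.0) -> AnalysisBundle:
    two_mols = int(np.asarray(traj.mol_index).max()) >= 1
    dist = distance_trace(traj) if two_mols else None
    return AnalysisBundle(
        distance=dist,
        contacts_intra=contact_map(traj, "intra", contact_cutoff),
        contacts_inter=contact_map(traj, "inter", contact_cutoff) if two_mols else None,
        rg=rg_series(traj),
        rg_hist=rg_distribution(traj),
        rmsd=rmsd_series(traj),
        rmsd2d=rmsd_2d(traj, stride=rmsd2d_stride),
        events=association_events(dist, d_on, d_off) if two_mols else None,
        times=traj.times.copy(),
    )
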