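"""Force-field parameters, presets and energy/force evaluation.

The potential is the two-term pairwise decomposition

    V(r_ij) = w_vdW * V_vdW(r_ij) + w_solv * V_solv(r_ij)

plus bonded terms, a directional backbone hydrogen-bond well and an
optional structure-based (Go) term. The hydrophobicity weights w_vdW and
w_solv are interpolated between a "short-range" value for residues nearby
in sequence (more hydrophobic, favouring local secondary structure) and a
"long-range" value for sequence-distant and intermolecular pairs.

V_vdW is a shifted-switched Lennard-Jones 12-6 with Lorentz-Berthelot
combination; V_solv is a pairwise Gaussian solvent-exclusion
(Lazaridis-Karplus-style) term. The hydrogen-bond energy is
eps_HB * cos^2(theta_NHO) * u(r_HO) with a 10-12 radial well u at 1.9 A,
the same well depth at every sequence separation.

All default numerical values are declared, overridable package defaults
(see docs/methods.md for provenance and rationale).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace

import numpy as np

from . import _kernels as K
from .errors import SingularityError

_EMPTY_I = np.empty((0, 2), dtype=np.int32)
_EMPTY_I3 = np.empty((0, 3), dtype=np.int32)
_EMPTY_I4 = np.empty((0, 4), dtype=np.int32)
_EMPTY_F = np.empty(0, dtype=np.float64)
_EMPTY_IV = np.empty(0, dtype=np.int32)


@dataclass(frozen=True)
class ForceFieldParams:
    """Every tunable force-field symbol, serialisable to a key-value file."""

    w_vdw_short: float = 1.0
    w_vdw_long: float = 0.8
    w_solv_short: float = 0.7
    w_solv_long: float = 1.0
    delta_short: int = 4  # sequence-separation plateau bounds
    delta_long: int = 8
    eps_hb: float = 2.0  # kcal/mol hydrogen-bond well depth
    eps_go: float = 1.0  # kcal/mol per native contact
    cutoff: float = 10.0  # A nonbonded cutoff
    switch_width: float = 2.0  # A, C1 switch region below the cutoff
    solv_scale: float = 0.15  # kcal/mol per Kyte-Doolittle unit (beads)
    solv_lambda: float = 2.0  # A Gaussian desolvation width
    k_bond: float = 30.0  # kcal/mol/A^2
    k_angle: float = 30.0  # kcal/mol/rad^2
    k_torsion: float = 3.0  # kcal/mol (peptide planarity restraints)
    scale_14: float = 0.5  # 1-4 nonbonded scaling
    hb_r0: float = 1.9  # A H...O well minimum
    hb_switch_start: float = 3.5  # A
    hb_cutoff: float = 4.5  # A
    preset_name: str = "default"

    def __post_init__(self):
        if self.w_vdw_short < 0 or self.w_vdw_long < 0 or self.w_solv_short < 0 or self.w_solv_long < 0:
            raise ValueError("omega weights must be nonnegative")
        if self.delta_short >= self.delta_long:
            raise ValueError("delta_short must be < delta_long")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def replace(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)

    def param_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# pacsab force-field parameters\n")
            for k, v in self.to_dict().items():
                fh.write(f"{k} = {v!r}\n")

    @classmethod
    def load(cls, path) -> "ForceFieldParams":
        import ast

        d = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                d[k.strip()] = ast.literal_eval(v.strip())
        return cls.from_dict(d)


_PRESETS = ("default", "server_2024", "unfolding")


def preset(name: str) -> ForceFieldParams:
    """Named parameter sets.

    ``default``
        the standard parametrisation.
    ``server_2024``
        default with both van der Waals weights reduced by 3%, slightly
        less hydrophobic: transient dimers dissociate faster, giving
        richer association/dissociation statistics.
    ``unfolding``
        very hydrophilic with very weak hydrogen bonding (w_vdW x 0.5,
        w_solv x 2.0, eps_HB x 0.2); used briefly to melt a folded input
        into a random coil before simulating a disordered protein.
    """
    base = ForceFieldParams()
    if name == "default":
        return base
    if name == "server_2024":
        return base.replace(
            w_vdw_short=base.w_vdw_short * 0.97,
            w_vdw_long=base.w_vdw_long * 0.97,
            preset_name="server_2024",
        )
    if name == "unfolding":
        return base.replace(
            w_vdw_short=base.w_vdw_short * 0.5,
            w_vdw_long=base.w_vdw_long * 0.5,
            w_solv_short=base.w_solv_short * 2.0,
            w_solv_long=base.w_solv_long * 2.0,
            eps_hb=base.eps_hb * 0.2,
            preset_name="unfolding",
        )
    raise ValueError(f"unknown preset {name!r}; available: {', '.join(_PRESETS)}")


def pair_weights(res_i: int, res_j: int, mol_i: int, mol_j: int,
                 params: ForceFieldParams) -> tuple[float, float]:
    """Effective (w_vdW, w_solv) for one particle pair.

    Intermolecular pairs always take the long-range values; intramolecular
    pairs interpolate linearly in sequence separation between the
    short-range plateau (more hydrophobic) and the long-range plateau."""
    if mol_i != mol_j:
        return params.w_vdw_long, params.w_solv_long
    d = abs(res_i - res_j)
    if d <= params.delta_short:
        return params.w_vdw_short, params.w_solv_short
    if d >= params.delta_long:
        return params.w_vdw_long, params.w_solv_long
    t = (d - params.delta_short) / (params.delta_long - params.delta_short)
    return (params.w_vdw_short + t * (params.w_vdw_long - params.w_vdw_short),
            params.w_solv_short + t * (params.w_solv_long - params.w_solv_short))


def vdw_energy_force(r: float, sigma_pair: float, eps_pair: float,
                     params: ForceFieldParams | None = None) -> tuple[float, float]:
    """Unweighted V_vdW(r) and dV/dr for one pair (shifted-switched LJ)."""
    p = params or ForceFieldParams()
    if r <= 0:
        raise ValueError("r must be positive")
    return K._lj_pair(r, sigma_pair, eps_pair, p.cutoff, p.switch_width)


def solvation_energy_force(r: float, contact: float, dg_i: float, dg_j: float,
                           params: ForceFieldParams | None = None) -> tuple[float, float]:
    """Unweighted V_solv(r) and dV/dr for one pair; ``contact`` is the pair
    contact distance (Lorentz-Berthelot sigma) where burial saturates."""
    p = params or ForceFieldParams()
    return K._solv_pair(r, contact, dg_i + dg_j, p.solv_lambda, p.cutoff, p.switch_width)


def hbond_energy_force(n_pos, h_pos, o_pos,
                       params: ForceFieldParams | None = None):
    """Directional hydrogen-bond energy and forces on (N, H, O).

    Geometric only; donor/acceptor eligibility (|i-j| >= 2 intramolecular,
    anything intermolecular) is enforced by the system-level evaluation.
    Returns (E, forces) with forces of shape (3, 3) rows N, H, O."""
    p = params or ForceFieldParams()
    pos = np.asarray([n_pos, h_pos, o_pos], dtype=float)
    f = np.zeros((3, 3))
    dN = np.array([0], dtype=np.int32)
    dH = np.array([1], dtype=np.int32)
    aO = np.array([2], dtype=np.int32)
    zero = np.array([0], dtype=np.int32)
    one = np.array([1], dtype=np.int32)
    out = K._forces(pos, 1e4, _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F,
                    _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_F,
                    p.solv_lambda, p.cutoff, p.switch_width,
                    _EMPTY_I, _EMPTY_F, p.k_bond,
                    _EMPTY_I3, _EMPTY_F, p.k_angle,
                    _EMPTY_I4, _EMPTY_F, p.k_torsion,
                    dN, dH, zero, zero, aO, zero, one,
                    p.eps_hb, p.hb_r0, p.hb_switch_start, p.hb_cutoff,
                    _EMPTY_IV, _EMPTY_IV, _EMPTY_F, _EMPTY_F, p.eps_go, f)
    return out[3], f


def go_energy_force(coords, pairs, r0, eps_go: float, weights=None):
    """Structure-based 12-10 term over native-contact particle pairs.

    Returns (E, forces) with forces shaped like ``coords``."""
    coords = np.asarray(coords, dtype=float)
    pairs = np.asarray(pairs, dtype=np.int32).reshape(-1, 2)
    r0 = np.asarray(r0, dtype=float)
    w = np.ones(len(pairs)) if weights is None else np.asarray(weights, dtype=float)
    f = np.zeros_like(coords)
    n = len(coords)
    out = K._forces(coords, 1e4, _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F,
                    _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_F,
                    3.5, 12.0, 2.0,
                    _EMPTY_I, _EMPTY_F, 0.0,
                    _EMPTY_I3, _EMPTY_F, 0.0,
                    _EMPTY_I4, _EMPTY_F, 0.0,
                    _EMPTY_IV, _EMPTY_IV, _EMPTY_IV, _EMPTY_IV,
                    _EMPTY_IV, _EMPTY_IV, _EMPTY_IV,
                    0.0, 1.9, 3.5, 4.5,
                    np.ascontiguousarray(pairs[:, 0]), np.ascontiguousarray(pairs[:, 1]),
                    r0, w, eps_go, f)
    return out[4], f


@dataclass
class EnergyReport:
    """Per-term energy decomposition (kcal/mol) and forces (kcal/mol/A)."""

    bonded: float
    vdw: float
    solvation: float
    hbond: float
    go: float
    forces: np.ndarray

    @property
    def total(self) -> float:
        return self.bonded + self.vdw + self.solvation + self.hbond + self.go

    def as_dict(self) -> dict:
        return {"bonded": self.bonded, "vdw": self.vdw, "solvation": self.solvation,
                "hbond": self.hbond, "go": self.go, "total": self.total}


@dataclass
class CompiledSystem:
    """Static kernel-ready arrays derived from a SystemModel + params."""

    L: float
    sigma: np.ndarray
    eps: np.ndarray
    dg: np.ndarray
    inv_m: np.ndarray
    excl: np.ndarray  # (N, N) int8: 0 include, 1 exclude, 2 scale-1/4
    resseq: np.ndarray
    mol: np.ndarray
    bonds: np.ndarray
    bond_b0: np.ndarray
    angles: np.ndarray
    ang_t0: np.ndarray
    tors: np.ndarray
    tor_p0: np.ndarray
    dN: np.ndarray
    dH: np.ndarray
    dres: np.ndarray
    dmol: np.ndarray
    aO: np.ndarray
    ares: np.ndarray
    amol: np.ndarray
    go_a: np.ndarray
    go_b: np.ndarray
    go_r0: np.ndarray
    go_w: np.ndarray


def compile_system(system, params: ForceFieldParams, use_go: bool = True) -> CompiledSystem:
    """Flatten a SystemModel into contiguous kernel arrays."""
    n = system.n_particles
    kinds = np.asarray(system.kinds)
    dg = np.where(kinds == 5, np.asarray(system.dg_unit) * params.solv_scale,
                  np.asarray(system.dg_unit)).astype(np.float64)
    excl = np.zeros((n, n), dtype=np.int8)
    adj = [[] for _ in range(n)]
    for a, b in np.asarray(system.bonds, dtype=int).reshape(-1, 2):
        adj[a].append(b)
        adj[b].append(a)
    for i in range(n):
        for j in adj[i]:
            excl[i, j] = 1  # 1-2
            for k in adj[j]:
                if k != i:
                    if excl[i, k] != 1:
                        excl[i, k] = 1  # 1-3
                    for l in adj[k]:
                        if l != j and l != i and excl[i, l] == 0:
                            excl[i, l] = 2  # 1-4, scaled
    np.fill_diagonal(excl, 1)
    # 1-2/1-3 dominate 1-4 when paths overlap: fix 2s that are also short paths
    # (handled above because 1 is never overwritten by 2)

    donors, accept = [], []
    res_names = system.res_names
    first_res_of_mol = set()
    seen = set()
    for ridx, m in zip(np.asarray(system.res_index), np.asarray(system.mol_index)):
        if m not in seen:
            seen.add(m)
            first_res_of_mol.add(int(ridx))
    by_res: dict = {}
    for i in range(n):
        by_res.setdefault(int(system.res_index[i]), {})[int(kinds[i])] = i
    for ridx, atoms in by_res.items():
        m = int(system.mol_index[atoms[0 if 0 in atoms else list(atoms)[0]]])
        seq = int(system.res_seq[atoms[list(atoms)[0]]])
        if 1 in atoms and 0 in atoms and ridx not in first_res_of_mol \
                and res_names[ridx] != "PRO":
            donors.append((atoms[0], atoms[1], seq, m))
        if 4 in atoms:
            accept.append((atoms[4], seq, m))
    dN = np.array([d[0] for d in donors], dtype=np.int32)
    dH = np.array([d[1] for d in donors], dtype=np.int32)
    dres = np.array([d[2] for d in donors], dtype=np.int32)
    dmol = np.array([d[3] for d in donors], dtype=np.int32)
    aO = np.array([a[0] for a in accept], dtype=np.int32)
    ares = np.array([a[1] for a in accept], dtype=np.int32)
    amol = np.array([a[2] for a in accept], dtype=np.int32)

    if use_go and system.go_pairs is not None and len(system.go_pairs):
        gp = np.asarray(system.go_pairs, dtype=np.int32).reshape(-1, 2)
        go_a = np.ascontiguousarray(gp[:, 0])
        go_b = np.ascontiguousarray(gp[:, 1])
        go_r0 = np.asarray(system.go_r0, dtype=np.float64)
        go_w = np.asarray(system.go_weight, dtype=np.float64)
    else:
        go_a = go_b = _EMPTY_IV
        go_r0 = go_w = _EMPTY_F

    L = system.box_L if system.box_L else 1e6
    return CompiledSystem(
        L=float(L),
        sigma=np.asarray(system.sigma, dtype=np.float64),
        eps=np.asarray(system.eps, dtype=np.float64),
        dg=dg,
        inv_m=1.0 / np.asarray(system.masses, dtype=np.float64),
        excl=excl,
        resseq=np.asarray(system.res_seq, dtype=np.int32),
        mol=np.asarray(system.mol_index, dtype=np.int32),
        bonds=np.asarray(system.bonds, dtype=np.int32).reshape(-1, 2),
        bond_b0=np.asarray(system.bond_b0, dtype=np.float64),
        angles=np.asarray(system.angles, dtype=np.int32).reshape(-1, 3),
        ang_t0=np.asarray(system.angle_t0, dtype=np.float64),
        tors=np.asarray(system.torsions, dtype=np.int32).reshape(-1, 4),
        tor_p0=np.asarray(system.torsion_phi0, dtype=np.float64),
        dN=dN, dH=dH, dres=dres, dmol=dmol, aO=aO, ares=ares, amol=amol,
        go_a=go_a, go_b=go_b, go_r0=go_r0, go_w=go_w,
    )


def total_energy_forces(system, params: ForceFieldParams,
                        coords=None, use_go: bool = True,
                        compiled: CompiledSystem | None = None) -> EnergyReport:
    """Evaluate the full potential and forces for a system configuration.

    Minimum-image periodic boundary conditions apply to all nonbonded
    terms; bonded and Go terms use direct (unwrapped) distances."""
    cs = compiled or compile_system(system, params, use_go=use_go)
    pos = np.ascontiguousarray(system.coords if coords is None else coords,
                               dtype=np.float64)
    pairs, pwv, pws, psc, psig, peps4, pdg, pshift = K._build_pairs(
        pos, cs.L, params.cutoff, cs.excl, cs.resseq, cs.mol,
        params.w_vdw_short, params.w_vdw_long, params.w_solv_short,
        params.w_solv_long, float(params.delta_short), float(params.delta_long),
        params.scale_14, cs.sigma, cs.eps, cs.dg, params.cutoff)
    f = np.zeros_like(pos)
    eb, ev, es, eh, eg, erri, errj = K._forces(
        pos, cs.L, pairs, pwv, pws, psc, psig, peps4, pdg, pshift,
        params.solv_lambda, params.cutoff, params.switch_width,
        cs.bonds, cs.bond_b0, params.k_bond,
        cs.angles, cs.ang_t0, params.k_angle,
        cs.tors, cs.tor_p0, params.k_torsion,
        cs.dN, cs.dH, cs.dres, cs.dmol, cs.aO, cs.ares, cs.amol,
        params.eps_hb, params.hb_r0, params.hb_switch_start, params.hb_cutoff,
        cs.go_a, cs.go_b, cs.go_r0, cs.go_w, params.eps_go, f)
    if erri >= 0:
        raise SingularityError(
            f"overlapping particles {erri} and {errj} (r < 0.1 A)")
    return EnergyReport(bonded=eb, vdw=ev, solvation=es, hbond=eh, go=eg, forces=f)
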