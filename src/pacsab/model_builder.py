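"""Map an atomistic structure to the coarse-grained representation
(atomistic backbone + one side-chain bead per residue), size and populate
the two-copy periodic box, and extract native contacts for the
structure-based term.

Bead nonbonded parameters are aggregated from the residue's side-chain
atoms (pairwise-additive construction); bonded equilibrium values are
measured from the input coordinates so any valid input structure is a
local minimum of the bonded terms, while stiffnesses live in
ForceFieldParams and are applied at evaluation time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _residues as R
from ._geometry import bond_angle, dihedral, place_atom
from .errors import ModelError, SetupError
from .io_formats import Structure

AVOGADRO = 6.02214076e23

_BB_ORDER = ("N", "H", "CA", "C", "O")


@dataclass
class SystemModel:
    """Coarse-grained particle system (one or two molecules)."""

    coords: np.ndarray  # (N, 3) A
    kinds: np.ndarray  # int8 codes, see _residues.KIND_CODES
    res_index: np.ndarray  # global residue index per particle
    res_seq: np.ndarray  # residue index within its chain
    mol_index: np.ndarray  # 0 or 1
    res_names: list  # per global residue, 3-letter
    masses: np.ndarray
    sigma: np.ndarray
    eps: np.ndarray
    dg_unit: np.ndarray  # backbone: kcal/mol; beads: Kyte-Doolittle units
    bonds: np.ndarray
    bond_b0: np.ndarray
    angles: np.ndarray
    angle_t0: np.ndarray  # cos(theta0) per angle (cosine-harmonic term)
    torsions: np.ndarray
    torsion_phi0: np.ndarray
    sequence: str
    n_res_per_chain: int
    box_L: float | None = None
    go_pairs: np.ndarray | None = None
    go_r0: np.ndarray | None = None
    go_weight: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    @property
    def n_molecules(self) -> int:
        return int(np.max(self.mol_index)) + 1 if self.n_particles else 0

    def with_box(self, L: float) -> "SystemModel":
        out = self.copy()
        out.box_L = float(L)
        return out

    def copy(self) -> "SystemModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def save(self, path) -> None:
        payload = {}
        for name in ("coords", "kinds", "res_index", "res_seq", "mol_index",
                     "masses", "sigma", "eps", "dg_unit", "bonds", "bond_b0",
                     "angles", "angle_t0", "torsions", "torsion_phi0"):
            payload[name] = np.asarray(getattr(self, name)).tolist()
        payload["res_names"] = list(self.res_names)
        payload["sequence"] = self.sequence
        payload["n_res_per_chain"] = self.n_res_per_chain
        payload["box_L"] = self.box_L
        for name in ("go_pairs", "go_r0", "go_weight"):
            v = getattr(self, name)
            payload[name] = None if v is None else np.asarray(v).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SystemModel":
        with open(path) as fh:
            d = json.load(fh)
        def arr(name, dtype, shape2=None):
            a = np.asarray(d[name], dtype=dtype)
            if shape2 and a.size == 0:
                a = a.reshape(0, shape2)
            return a
        return cls(
            coords=arr("coords", float),
            kinds=arr("kinds", np.int8),
            res_index=arr("res_index", np.int32),
            res_seq=arr("res_seq", np.int32),
            mol_index=arr("mol_index", np.int32),
            res_names=list(d["res_names"]),
            masses=arr("masses", float),
            sigma=arr("sigma", float),
            eps=arr("eps", float),
            dg_unit=arr("dg_unit", float),
            bonds=arr("bonds", np.int32, 2),
            bond_b0=arr("bond_b0", float),
            angles=arr("angles", np.int32, 3),
            angle_t0=arr("angle_t0", float),
            torsions=arr("torsions", np.int32, 4),
            torsion_phi0=arr("torsion_phi0", float),
            sequence=d["sequence"],
            n_res_per_chain=d["n_res_per_chain"],
            box_L=d["box_L"],
            go_pairs=None if d["go_pairs"] is None else np.asarray(d["go_pairs"], dtype=np.int32).reshape(-1, 2),
            go_r0=None if d["go_r0"] is None else np.asarray(d["go_r0"], dtype=float),
            go_weight=None if d["go_weight"] is None else np.asarray(d["go_weight"], dtype=float),
        )


@dataclass
class NativeContactList:
    """Intramolecular residue pairs in contact in a reference structure."""

    pairs: np.ndarray  # (n, 2) residue indices, |i-j| >= 3
    r0_ca: np.ndarray  # reference CA-CA distance (A)
    r0_sc: np.ndarray  # reference SC-SC (CB-proxy) distance, nan if either side lacks a bead
    depth: np.ndarray = field(default=None)  # per-contact well weight

    def __post_init__(self):
        if self.depth is None:
            self.depth = np.ones(len(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def build_pacsab_model(structure: Structure, params=None, bead_site: str = "centroid",
                       max_residues: int = 200, allow_long: bool = False) -> SystemModel:
    """Build the single-copy coarse-grained model from an atomistic chain.

    Backbone atoms N, H, CA, C, O keep their input coordinates; the side
    chain becomes one bead at the side-chain heavy-atom centroid (or at CB
    with ``bead_site='cb'``); glycine gets no bead; proline keeps N
    without H. Raises ModelError for unknown residues or chains longer
    than ``max_residues`` (a tool speed constraint; override with
    ``allow_long=True``)."""
    structure.validate()
    nres = structure.n_residues
    if nres > max_residues and not allow_long:
        raise ModelError(
            f"chain has {nres} residues; the tool accepts at most {max_residues} "
            "(pass allow_long=True to override)")
    unknown = sorted({r for r in structure.res_names if r not in R.THREE_TO_ONE})
    if unknown:
        raise ModelError(
            f"unknown residue name(s) {', '.join(unknown)}; supported: "
            + ", ".join(sorted(R.THREE_TO_ONE)))

    coords, kinds, res_index, masses, sigma, eps, dg = [], [], [], [], [], [], []
    index_of: dict = {}  # (res, kind_name) -> particle index

    for ires in range(nres):
        rname3 = structure.res_names[ires]
        one = R.THREE_TO_ONE[rname3]
        atom_idx = {structure.atom_names[i]: i for i in structure.residue_atom_indices(ires)}
        has_h = "H" in atom_idx and rname3 != "PRO"
        for kname in _BB_ORDER:
            if kname == "H" and not has_h:
                continue
            if kname not in atom_idx:
                raise ModelError(f"residue {rname3}{ires + 1} lacks backbone atom {kname}")
            m, s, e, g = R.BACKBONE_PARAMS[kname]
            if kname == "N" and not has_h:
                m = 14.0  # no repartitioned H on this nitrogen
            if kname == "CA" and one == "G":
                m = 14.0  # glycine's extra side H folded into CA
            index_of[(ires, kname)] = len(coords)
            coords.append(structure.coords[atom_idx[kname]])
            kinds.append(R.KIND_CODES[kname])
            res_index.append(ires)
            masses.append(m)
            sigma.append(s)
            eps.append(e)
            dg.append(g)
        if one != "G":
            sc_names = [nm for nm in atom_idx
                        if nm not in R.BACKBONE_ATOM_NAMES and not nm.startswith("H")]
            if bead_site == "cb" and "CB" in atom_idx:
                pos = structure.coords[atom_idx["CB"]]
            elif sc_names:
                pos = structure.coords[[atom_idx[nm] for nm in sc_names]].mean(axis=0)
            else:
                warnings.warn(f"residue {rname3}{ires + 1} has no side-chain atoms; "
                              "bead placed at the ideal CB position")
                n_, ca_, c_ = (structure.coords[atom_idx[k]] for k in ("N", "CA", "C"))
                pos = place_atom(c_, n_, ca_, 1.53, np.deg2rad(110.5), np.deg2rad(-122.6))
            index_of[(ires, "SC")] = len(coords)
            coords.append(pos)
            kinds.append(R.KIND_CODES["SC"])
            res_index.append(ires)
            masses.append(R.bead_mass(one))
            sigma.append(R.bead_sigma(one))
            eps.append(R.bead_epsilon(one))
            dg.append(R.KYTE_DOOLITTLE[one])

    coords = np.asarray(coords, dtype=float)

    bonds = []
    for ires in range(nres):
        for a, b in (("N", "H"), ("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "SC")):
            if (ires, a) in index_of and (ires, b) in index_of:
                bonds.append((index_of[(ires, a)], index_of[(ires, b)]))
        if ires + 1 < nres:
            bonds.append((index_of[(ires, "C")], index_of[(ires + 1, "N")]))
    bonds = np.asarray(bonds, dtype=np.int32)
    bond_b0 = np.array([np.linalg.norm(coords[a] - coords[b]) for a, b in bonds])

    adj = [[] for _ in range(len(coords))]
    for a, b in bonds:
        adj[a].append(int(b))
        adj[b].append(int(a))
    angles, angle_t0 = [], []
    for j in range(len(coords)):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                i, k = nb[x], nb[y]
                t0 = bond_angle(coords[i], coords[j], coords[k])
                if t0 > np.deg2rad(175.0):
                    continue  # nearly collinear reference: skip the restraint
                angles.append((i, j, k))
                angle_t0.append(np.cos(t0))  # cosine-harmonic angle term
    angles = np.asarray(angles, dtype=np.int32).reshape(-1, 3)
    angle_t0 = np.asarray(angle_t0)

    torsions, phi0 = [], []
    def add_torsion(quad):
        p = [index_of.get(k) for k in quad]
        if None in p:
            return
        torsions.append(tuple(p))
        phi0.append(dihedral(*(coords[i] for i in p)))
    for ires in range(nres - 1):
        # peptide-bond planarity (omega) and carbonyl-O improper
        add_torsion(((ires, "CA"), (ires, "C"), (ires + 1, "N"), (ires + 1, "CA")))
        add_torsion(((ires + 1, "N"), (ires, "CA"), (ires, "C"), (ires, "O")))
    for ires in range(1, nres):
        # amide-H improper: H follows the preceding carbonyl, not phi
        add_torsion(((ires - 1, "C"), (ires, "CA"), (ires, "N"), (ires, "H")))
    torsions = np.asarray(torsions, dtype=np.int32).reshape(-1, 4)
    phi0 = np.asarray(phi0)

    return SystemModel(
        coords=coords,
        kinds=np.asarray(kinds, dtype=np.int8),
        res_index=np.asarray(res_index, dtype=np.int32),
        res_seq=np.asarray(res_index, dtype=np.int32),
        mol_index=np.zeros(len(coords), dtype=np.int32),
        res_names=list(structure.res_names),
        masses=np.asarray(masses),
        sigma=np.asarray(sigma),
        eps=np.asarray(eps),
        dg_unit=np.asarray(dg),
        bonds=bonds,
        bond_b0=bond_b0,
        angles=angles,
        angle_t0=angle_t0,
        torsions=torsions,
        torsion_phi0=phi0,
        sequence=structure.sequence,
        n_res_per_chain=nres,
    )


def box_side_from_concentration(concentration_mM: float, n_molecules: int = 2) -> float:
    """Cubic box side (A) holding ``n_molecules`` at the given molar
    concentration: C = n / (N_A L^3)."""
    if concentration_mM <= 0:
        raise ValueError("concentration must be positive")
    c_molar = concentration_mM / 1000.0
    L_dm = (n_molecules / (AVOGADRO * c_molar)) ** (1.0 / 3.0)
    return L_dm * 1e9  # dm -> A


def concentration_from_box(L_angstrom: float, n_molecules: int = 2) -> float:
    """Exact molar inverse of :func:`box_side_from_concentration` (mM)."""
    if L_angstrom <= 0:
        raise ValueError("box side must be positive")
    L_dm = L_angstrom * 1e-9
    return n_molecules / (AVOGADRO * L_dm ** 3) * 1000.0


def min_intercopy_distance(coords1, coords2, L) -> float:
    d = coords1[:, None, :] - coords2[None, :, :]
    d -= L * np.floor(d / L + 0.5)
    return float(np.sqrt((d ** 2).sum(axis=2)).min())


def replicate_with_offset(model: SystemModel, offset=None, L: float | None = None) -> SystemModel:
    """Replicate the single-copy model into a two-molecule periodic box.

    The copy is rigidly translated by ``offset`` (default (L/2, L/2, L/2),
    the maximal separation in a cubic box); both molecules are wrapped
    rigidly so their CA centroids lie in [0, L). A setup with minimum
    inter-copy (minimum-image) distance below 4 A is rejected."""
    if model.n_molecules != 1:
        raise SetupError("replicate_with_offset needs a single-copy model")
    if L is None:
        L = model.box_L
    if not L or L <= 0:
        raise SetupError("a positive box side L is required")
    L = float(L)
    offset = np.full(3, L / 2.0) if offset is None else np.asarray(offset, dtype=float)

    n = model.n_particles
    nres = model.n_res_per_chain
    c1 = model.coords.copy()
    c2 = model.coords + offset
    ca = model.kinds == R.KIND_CODES["CA"]
    for c in (c1, c2):
        cent = c[ca].mean(axis=0)
        c -= L * np.floor(cent / L)
    dmin = min_intercopy_distance(c1, c2, L)
    if dmin < 4.0:
        raise SetupError(
            f"inter-copy clash: minimum distance {dmin:.2f} A < 4 A; "
            "choose a larger offset and rebuild the setup")

    def dup2(a, off):
        a = np.asarray(a)
        return np.concatenate([a, a + off]) if a.size else a

    out = SystemModel(
        coords=np.vstack([c1, c2]),
        kinds=np.concatenate([model.kinds] * 2),
        res_index=np.concatenate([model.res_index, model.res_index + nres]).astype(np.int32),
        res_seq=np.concatenate([model.res_seq] * 2),
        mol_index=np.concatenate([np.zeros(n, np.int32), np.ones(n, np.int32)]),
        res_names=list(model.res_names) * 2,
        masses=np.concatenate([model.masses] * 2),
        sigma=np.concatenate([model.sigma] * 2),
        eps=np.concatenate([model.eps] * 2),
        dg_unit=np.concatenate([model.dg_unit] * 2),
        bonds=dup2(model.bonds, n).astype(np.int32).reshape(-1, 2),
        bond_b0=np.concatenate([model.bond_b0] * 2),
        angles=dup2(model.angles, n).astype(np.int32).reshape(-1, 3),
        angle_t0=np.concatenate([model.angle_t0] * 2),
        torsions=dup2(model.torsions, n).astype(np.int32).reshape(-1, 4),
        torsion_phi0=np.concatenate([model.torsion_phi0] * 2),
        sequence=model.sequence,
        n_res_per_chain=nres,
        box_L=L,
    )
    if model.go_pairs is not None and len(model.go_pairs):
        out.go_pairs = dup2(model.go_pairs, n).astype(np.int32).reshape(-1, 2)
        out.go_r0 = np.concatenate([model.go_r0] * 2)
        out.go_weight = np.concatenate([model.go_weight] * 2)
    return out


def extract_native_contacts(structure: Structure, cutoff: float = 8.0) -> NativeContactList:
    """Residue pairs (|i-j| >= 3) whose minimum heavy-atom distance in the
    reference structure is below ``cutoff``; reference distances are the
    CA-CA separation and, where both residues have a side chain, the CB
    (bead-proxy) separation."""
    structure.validate()
    nres = structure.n_residues
    heavy = [[i for i in structure.residue_atom_indices(r)
              if not structure.atom_names[i].startswith("H")] for r in range(nres)]
    pairs, r0_ca, r0_sc = [], [], []
    for i in range(nres):
        for j in range(i + 3, nres):
            di = structure.coords[heavy[i]][:, None, :] - structure.coords[heavy[j]][None, :, :]
            if np.sqrt((di ** 2).sum(axis=2)).min() >= cutoff:
                continue
            pairs.append((i, j))
            r0_ca.append(np.linalg.norm(
                structure.coords[structure.atom_index(i, "CA")]
                - structure.coords[structure.atom_index(j, "CA")]))
            try:
                cb_i = structure.atom_index(i, "CB")
                cb_j = structure.atom_index(j, "CB")
                r0_sc.append(np.linalg.norm(structure.coords[cb_i] - structure.coords[cb_j]))
            except KeyError:
                r0_sc.append(np.nan)
    return NativeContactList(
        pairs=np.asarray(pairs, dtype=np.int32).reshape(-1, 2),
        r0_ca=np.asarray(r0_ca),
        r0_sc=np.asarray(r0_sc),
    )


def apply_native_contacts(model: SystemModel, contacts: NativeContactList) -> SystemModel:
    """Attach structure-based wells to a single-copy model: one CA-CA well
    per contact plus an SC-SC well where both beads exist."""
    if model.n_molecules != 1:
        raise SetupError("attach native contacts before replication")
    out = model.copy()
    by_res: dict = {}
    for idx in range(model.n_particles):
        by_res.setdefault(int(model.res_index[idx]), {})[int(model.kinds[idx])] = idx
    ca_code = R.KIND_CODES["CA"]
    sc_code = R.KIND_CODES["SC"]
    gp, gr, gw = [], [], []
    for (i, j), rca, rsc, w in zip(contacts.pairs, contacts.r0_ca,
                                   contacts.r0_sc, contacts.depth):
        gp.append((by_res[int(i)][ca_code], by_res[int(j)][ca_code]))
        gr.append(rca)
        gw.append(w)
        if np.isfinite(rsc) and sc_code in by_res[int(i)] and sc_code in by_res[int(j)]:
            gp.append((by_res[int(i)][sc_code], by_res[int(j)][sc_code]))
            gr.append(np.linalg.norm(model.coords[by_res[int(i)][sc_code]]
                                     - model.coords[by_res[int(j)][sc_code]]))
            gw.append(w)
    out.go_pairs = np.asarray(gp, dtype=np.int32).reshape(-1, 2)
    out.go_r0 = np.asarray(gr)
    out.go_weight = np.asarray(gw)
    return out
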