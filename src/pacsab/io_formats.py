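"""Structure and trajectory I/O.

Structures are read from GRO (GROMACS fixed-column, nm) or PDB (ATOM
records, A) files into a :class:`Structure`; all internal coordinates are
Angstrom and picoseconds, unit conversion happens only at the file
boundary. Trajectories use the package's own binary container (explicit
header, bit-exact round trip); checkpoints are plain text with an embedded
force-field parameter block so a restarted run continues bit-identically.

Dialect decisions: velocities columns are accepted but never written; the
box is always cubic; residue numbering is normalised to 1..N contiguous on
input (original numbers kept in a provenance map); a missing backbone
amide H is reconstructed from ideal geometry (proline and nothing else is
H-free; the N-terminal H exists as a particle but never donates hydrogen
bonds).
"""

from __future__ import annotations

import ast
import json
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import amide_h_position, place_atom
from ._residues import KIND_NAMES, THREE_TO_ONE
from .errors import IntegrityError, ModelError, ParseError

_SOLVENT_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "TIP4", "NA", "CL", "NA+", "CL-", "K+", "MG", "ION"}

_TRAJ_MAGIC = b"PACSABT1"


@dataclass
class Structure:
    """A single-chain atomistic protein structure (coordinates in A)."""

    chain_id: str
    res_names: list  # 3-letter, one per residue
    atom_names: list  # one per atom
    atom_res: np.ndarray  # 0-based residue index per atom
    coords: np.ndarray  # (n_atoms, 3) A
    box: float | None = None  # cubic box side, A
    original_resids: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r, "X") for r in self.res_names)

    def residue_atom_indices(self, ires: int) -> np.ndarray:
        return np.nonzero(self.atom_res == ires)[0]

    def atom_index(self, ires: int, name: str) -> int:
        for i in self.residue_atom_indices(ires):
            if self.atom_names[i] == name:
                return int(i)
        raise KeyError(f"residue {ires + 1} has no atom {name!r}")

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise ModelError("empty structure")
        if not np.all(np.isfinite(self.coords)):
            raise ModelError("non-finite coordinates")
        missing = []
        for ires in range(self.n_residues):
            names = {self.atom_names[i] for i in self.residue_atom_indices(ires)}
            lack = {"N", "CA", "C", "O"} - names
            if lack:
                missing.append(f"{self.res_names[ires]}{ires + 1} (missing {','.join(sorted(lack))})")
        if missing:
            raise ModelError("residues missing backbone atoms: " + "; ".join(missing))

    def copy(self) -> "Structure":
        return Structure(
            chain_id=self.chain_id,
            res_names=list(self.res_names),
            atom_names=list(self.atom_names),
            atom_res=self.atom_res.copy(),
            coords=self.coords.copy(),
            box=self.box,
            original_resids=dict(self.original_resids),
        )


def _renumber(res_ids: list, res_names: list) -> tuple[np.ndarray, list, dict]:
    """Collapse per-atom (orig_resid, resname) runs into contiguous 0-based
    residue indices; returns per-atom index array, residue names, provenance."""
    atom_res = np.empty(len(res_ids), dtype=np.int32)
    names: list = []
    prov: dict = {}
    prev = None
    for i, key in enumerate(res_ids):
        if key != prev:
            names.append(res_names[i])
            prov[len(names)] = key[0]
            prev = key
        atom_res[i] = len(names) - 1
    return atom_res, names, prov


def _ensure_amide_h(s: Structure) -> None:
    """Reconstruct missing backbone amide hydrogens in place."""
    new_names, new_res, new_xyz = [], [], []
    for ires in range(s.n_residues):
        if s.res_names[ires] == "PRO":
            continue
        names = {s.atom_names[i] for i in s.residue_atom_indices(ires)}
        if "H" in names:
            continue
        n = s.coords[s.atom_index(ires, "N")]
        ca = s.coords[s.atom_index(ires, "CA")]
        if ires > 0:
            h = amide_h_position(n, ca, s.coords[s.atom_index(ires - 1, "C")])
        else:
            c = s.coords[s.atom_index(ires, "C")]
            h = place_atom(c, ca, n, 1.01, np.deg2rad(109.5), np.pi)
        new_names.append("H")
        new_res.append(ires)
        new_xyz.append(h)
    if not new_names:
        return
    # insert each H directly after its residue's N to keep a tidy atom order
    order = []
    extra = {r: (nm, xyz) for nm, r, xyz in zip(new_names, new_res, new_xyz)}
    names_out, res_out, xyz_out = [], [], []
    for i in range(s.n_atoms):
        names_out.append(s.atom_names[i])
        res_out.append(int(s.atom_res[i]))
        xyz_out.append(s.coords[i])
        r = int(s.atom_res[i])
        if s.atom_names[i] == "N" and r in extra:
            nm, xyz = extra.pop(r)
            names_out.append(nm)
            res_out.append(r)
            xyz_out.append(xyz)
    del order
    s.atom_names = names_out
    s.atom_res = np.asarray(res_out, dtype=np.int32)
    s.coords = np.asarray(xyz_out, dtype=float)


def read_gro(path) -> Structure:
    """Read a GROMACS .gro file (fixed columns, nm) into a Structure (A)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: too short to be a GRO file")
    try:
        n_declared = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"{path}, line 2: expected atom count, got {lines[1]!r}") from exc
    body = lines[2:2 + n_declared]
    if len(body) != n_declared or len(lines) < 3 + n_declared:
        raise IntegrityError(
            f"{path}: declared {n_declared} atoms but file holds {max(len(lines) - 3, 0)}"
        )
    res_keys, res_names, atom_names, xyz = [], [], [], []
    for lineno, line in enumerate(body, start=3):
        if len(line) < 44:
            raise ParseError(f"{path}, line {lineno}: GRO record shorter than 44 columns")
        try:
            resid = int(line[0:5])
            resname = line[5:10].strip()
            aname = line[10:15].strip()
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: malformed fixed-column fields") from exc
        if resname in _SOLVENT_RESNAMES:
            continue
        res_keys.append((resid, resname))
        res_names.append(resname)
        atom_names.append(aname)
        xyz.append((x * 10.0, y * 10.0, z * 10.0))  # nm -> A
    if len(res_keys) < len(body):
        warnings.warn("solvent/ion residues stripped on read")
    try:
        box_fields = [float(t) for t in lines[2 + n_declared].split()]
    except ValueError as exc:
        raise ParseError(f"{path}, line {3 + n_declared}: malformed box line") from exc
    box = box_fields[0] * 10.0 if box_fields and box_fields[0] > 0 else None
    atom_res, names, prov = _renumber(res_keys, res_names)
    s = Structure("A", names, atom_names, atom_res, np.asarray(xyz, dtype=float), box, prov)
    s.validate()
    _ensure_amide_h(s)
    return s


def write_gro(structure_or_frame, path, box: float | None = None, title: str = "pacsab") -> None:
    """Write a Structure (or a SystemModel-like frame carrying ``kinds``,
    ``res_index``, ``res_names``, ``coords``) as a GRO file (nm, 3 decimals).

    Byte output is deterministic for identical input; velocities are never
    written; the box is cubic (box side in A, written in nm)."""
    names, resnames, res_idx, coords = _as_records(structure_or_frame)
    if len(names) == 0:
        raise ModelError("refusing to write an empty structure")
    if box is None:
        box = getattr(structure_or_frame, "box", None) or getattr(structure_or_frame, "box_L", None) or 0.0
    with open(path, "w") as fh:
        fh.write(f"{title}\n{len(names):5d}\n")
        for i in range(len(names)):
            r = int(res_idx[i])
            x, y, z = coords[i] / 10.0
            fh.write(
                f"{(r + 1) % 100000:5d}{resnames[r][:5]:<5s}{names[i][:5]:>5s}"
                f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        b = (box or 0.0) / 10.0
        fh.write(f"{b:10.5f}{b:10.5f}{b:10.5f}\n")


def _as_records(obj):
    if isinstance(obj, Structure):
        return obj.atom_names, obj.res_names, obj.atom_res, obj.coords
    if hasattr(obj, "kinds"):
        names = [("SCB" if int(k) == 5 else KIND_NAMES[int(k)]) for k in obj.kinds]
        return names, obj.res_names, obj.res_index, obj.coords
    raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_pdb(path) -> Structure:
    """Read the first model of a PDB file (ATOM records only)."""
    res_keys, res_names, atom_names, xyz = [], [], [], []
    chains = set()
    in_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model += 1
                if in_model > 1:
                    break
            elif rec == "ENDMDL":
                break
            elif rec == "ATOM":
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}, line {lineno}: ATOM record shorter than 54 columns")
                altloc = line[16]
                if altloc not in (" ", "A"):
                    continue
                resname = line[17:20].strip()
                if resname in _SOLVENT_RESNAMES:
                    continue
                name = line[12:16].strip()
                if name.startswith("H") and name not in ("H",):
                    continue  # keep only the amide H; other hydrogens are implicit
                chains.add(line[21])
                try:
                    resid = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise ParseError(f"{path}, line {lineno}: malformed ATOM fields") from exc
                res_keys.append((resid, resname))
                res_names.append(resname)
                atom_names.append(name)
                xyz.append((x, y, z))
    if not atom_names:
        raise ParseError(f"{path}: no ATOM records found")
    if len(chains) > 1:
        raise ModelError(
            f"{path}: {len(chains)} chains found; the toolkit takes a single chain and replicates it itself"
        )
    ids = [k[0] for k in res_keys]
    uniq = sorted(set(ids))
    if uniq != list(range(uniq[0], uniq[0] + len(uniq))):
        warnings.warn("non-contiguous residue numbering; renumbered from 1")
    atom_res, names, prov = _renumber(res_keys, res_names)
    s = Structure(chains.pop() if chains else "A", names, atom_names, atom_res,
                  np.asarray(xyz, dtype=float), None, prov)
    s.validate()
    _ensure_amide_h(s)
    return s


def write_pdb(structure_or_frame, path, box: float | None = None) -> None:
    """Write ATOM records (A, 3 decimals). Used for the two-copy setup
    confirmation snapshot as well as plain structures."""
    names, resnames, res_idx, coords = _as_records(structure_or_frame)
    if len(names) == 0:
        raise ModelError("refusing to write an empty structure")
    mol = getattr(structure_or_frame, "mol_index", None)
    with open(path, "w") as fh:
        if box:
            b = float(box)
            fh.write(f"CRYST1{b:9.3f}{b:9.3f}{b:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for i in range(len(names)):
            r = int(res_idx[i])
            chain = "AB"[int(mol[i])] if mol is not None else "A"
            nm = names[i]
            nm_field = f" {nm:<3s}" if len(nm) < 4 else nm[:4]
            x, y, z = coords[i]
            fh.write(
                f"ATOM  {(i + 1) % 100000:5d} {nm_field} {resnames[r][:3]:>3s} {chain}"
                f"{(r + 1) % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
        fh.write("END\n")


@dataclass
class Trajectory:
    """Fixed-count frame store with particle metadata and provenance."""

    coords: np.ndarray  # (n_frames, n_particles, 3) A
    times: np.ndarray  # (n_frames,) ps
    box: float  # A
    kinds: np.ndarray  # int8 particle kind codes
    res_index: np.ndarray  # int32 global residue index per particle
    mol_index: np.ndarray  # int32 molecule index per particle
    masses: np.ndarray  # amu
    metadata: dict = field(default_factory=dict)
    final_state: object = None  # not serialised

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def backbone_only(self) -> "Trajectory":
        """Drop the coarse-grained side-chain beads (the exported-download
        resolution)."""
        keep = np.nonzero(self.kinds != 5)[0]
        return Trajectory(
            coords=self.coords[:, keep, :].copy(),
            times=self.times.copy(),
            box=self.box,
            kinds=self.kinds[keep].copy(),
            res_index=self.res_index[keep].copy(),
            mol_index=self.mol_index[keep].copy(),
            masses=self.masses[keep].copy(),
            metadata=dict(self.metadata, backbone_only=True),
        )


def write_trajectory(traj: Trajectory, path, backbone_only: bool = False) -> None:
    """Write the binary trajectory container (lossless float64 round trip)."""
    t = traj.backbone_only() if backbone_only else traj
    header = {
        "n_frames": int(t.n_frames),
        "n_particles": int(t.n_particles),
        "box": float(t.box),
        "metadata": t.metadata,
    }
    hbytes = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_TRAJ_MAGIC)
        fh.write(struct.pack("<I", 1))  # version
        fh.write(struct.pack("<I", len(hbytes)))
        fh.write(hbytes)
        fh.write(np.ascontiguousarray(t.kinds, dtype=np.int8).tobytes())
        fh.write(np.ascontiguousarray(t.res_index, dtype=np.int32).tobytes())
        fh.write(np.ascontiguousarray(t.mol_index, dtype=np.int32).tobytes())
        fh.write(np.ascontiguousarray(t.masses, dtype=np.float64).tobytes())
        fh.write(np.ascontiguousarray(t.times, dtype=np.float64).tobytes())
        fh.write(np.ascontiguousarray(t.coords, dtype=np.float64).tobytes())


def read_trajectory(path) -> Trajectory:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:8] != _TRAJ_MAGIC:
        raise ParseError(f"{path}: not a pacsab trajectory (bad magic)")
    (version,) = struct.unpack_from("<I", data, 8)
    if version != 1:
        raise ParseError(f"{path}: unsupported container version {version}")
    (hlen,) = struct.unpack_from("<I", data, 12)
    header = json.loads(data[16:16 + hlen].decode())
    n_frames, n = header["n_frames"], header["n_particles"]
    off = 16 + hlen
    def take(dtype, count):
        nonlocal off
        nbytes = np.dtype(dtype).itemsize * count
        if off + nbytes > len(data):
            raise IntegrityError(f"{path}: truncated before particle metadata")
        arr = np.frombuffer(data[off:off + nbytes], dtype=dtype).copy()
        off += nbytes
        return arr
    kinds = take(np.int8, n)
    res_index = take(np.int32, n)
    mol_index = take(np.int32, n)
    masses = take(np.float64, n)
    times = take(np.float64, n_frames)
    frame_bytes = n * 3 * 8
    avail = len(data) - off
    complete = avail // frame_bytes
    if complete < n_frames:
        raise IntegrityError(
            f"{path}: truncated mid-frame; last complete frame is {complete - 1} "
            f"of {n_frames} declared"
        )
    coords = np.frombuffer(data[off:off + n_frames * frame_bytes], dtype=np.float64)
    coords = coords.reshape(n_frames, n, 3).copy()
    return Trajectory(coords, times, header["box"], kinds, res_index, mol_index,
                      masses, header["metadata"])


@dataclass
class DynState:
    """Full dynamic state: enough to continue a run bit-identically."""

    positions: np.ndarray  # (N, 3) A, unwrapped
    velocities: np.ndarray  # (N, 3) A/ps
    rng_state: dict  # numpy BitGenerator state
    step: int
    time_ps: float
    params: object  # ForceFieldParams
    frames_done: int = 0


def write_restart(state: DynState, path) -> None:
    """Plain-text checkpoint; float fields use repr (exact round trip)."""
    from .force_field import ForceFieldParams  # local import avoids a cycle

    assert isinstance(state.params, ForceFieldParams)
    with open(path, "w") as fh:
        fh.write("# pacsab checkpoint v1\n")
        fh.write(f"n_particles: {state.positions.shape[0]}\n")
        fh.write(f"step: {state.step}\n")
        fh.write(f"time_ps: {float(state.time_ps)!r}\n")
        fh.write(f"frames_done: {state.frames_done}\n")
        fh.write(f"rng: {json.dumps(state.rng_state)}\n")
        fh.write(f"param_hash: {state.params.param_hash()}\n")
        fh.write("[params]\n")
        for k, v in state.params.to_dict().items():
            fh.write(f"{k} = {v!r}\n")
        fh.write("[positions]\n")
        for row in state.positions:
            fh.write(f"{float(row[0])!r} {float(row[1])!r} {float(row[2])!r}\n")
        fh.write("[velocities]\n")
        for row in state.velocities:
            fh.write(f"{float(row[0])!r} {float(row[1])!r} {float(row[2])!r}\n")


def read_restart(path) -> DynState:
    from .force_field import ForceFieldParams

    head: dict = {}
    params_kv: dict = {}
    pos, vel = [], []
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            if section is None:
                k, _, v = line.partition(":")
                head[k.strip()] = v.strip()
            elif section == "params":
                k, _, v = line.partition("=")
                params_kv[k.strip()] = ast.literal_eval(v.strip())
            elif section == "positions":
                pos.append([float(t) for t in line.split()])
            elif section == "velocities":
                vel.append([float(t) for t in line.split()])
    n = int(head["n_particles"])
    positions = np.asarray(pos, dtype=float)
    velocities = np.asarray(vel, dtype=float)
    if positions.shape != (n, 3) or velocities.shape != (n, 3):
        raise IntegrityError(f"{path}: checkpoint arrays do not match n_particles={n}")
    params = ForceFieldParams.from_dict(params_kv)
    return DynState(
        positions=positions,
        velocities=velocities,
        rng_state=json.loads(head["rng"]),
        step=int(head["step"]),
        time_ps=float(head["time_ps"]),
        params=params,
        frames_done=int(head.get("frames_done", 0)),
    )
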