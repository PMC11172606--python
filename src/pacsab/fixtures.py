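"""Synthetic polypeptide structures and distance traces with known
properties, so every part of the toolkit is testable without any external
files.

Backbones are built by internal-coordinate chain extension with canonical
bond lengths and angles; helix means (phi, psi) = (-57, -47) deg, extended
(-120, 120) deg, and coil draws (phi, psi) from the broad allowed regions
of the Ramachandran map with seeded clash rejection — the same idea as
melting a folded input into a random coil before simulating a disordered
protein, but constructed directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import amide_h_position, place_atom
from ._residues import ONE_TO_THREE
from .analysis import DistanceTrace
from .io_formats import Structure

# canonical backbone internal coordinates (A, deg)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_N_H, _B_CA_CB = 1.231, 1.01, 1.53
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 109.5, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5

_PHI_PSI = {"helix": (-57.0, -47.0), "extended": (-120.0, 120.0)}


@dataclass(frozen=True)
class PeptideSpec:
    sequence: str
    conformation: str = "helix"  # helix | extended | coil
    seed: int = 0


def _coil_sampler(rng):
    def draw():
        region = rng.choice(3, p=[0.45, 0.45, 0.10])
        if region == 0:  # alpha basin
            return rng.normal(-63.0, 15.0), rng.normal(-43.0, 15.0)
        if region == 1:  # beta basin
            return rng.normal(-120.0, 25.0), rng.normal(135.0, 25.0)
        return rng.normal(57.0, 15.0), rng.normal(47.0, 15.0)  # left-handed alpha
    return draw


def make_polypeptide(spec_or_sequence, conformation: str = "helix",
                     seed: int = 0) -> Structure:
    """Build an ideal-geometry polypeptide Structure (atoms N, H, CA, C,
    O, CB per residue; glycine has no CB, proline no H). Deterministic for
    a fixed (sequence, conformation, seed)."""
    if isinstance(spec_or_sequence, PeptideSpec):
        seq = spec_or_sequence.sequence
        conformation = spec_or_sequence.conformation
        seed = spec_or_sequence.seed
    else:
        seq = str(spec_or_sequence)
    if not (1 <= len(seq) <= 200):
        raise ValueError("sequence length must be in [1, 200]")
    bad = sorted({c for c in seq if c not in ONE_TO_THREE})
    if bad:
        raise ValueError(f"invalid amino-acid letter(s): {', '.join(bad)}")
    if conformation not in ("helix", "extended", "coil"):
        raise ValueError("conformation must be helix, extended or coil")

    rng = np.random.default_rng(seed)
    draw = _coil_sampler(rng) if conformation == "coil" else None
    nres = len(seq)

    def backbone_for(angles):
        """(phi_i, psi_i) list -> N/CA/C positions for len(angles) residues."""
        N = [np.array([0.0, 0.0, 0.0])]
        CA = [np.array([_B_N_CA, 0.0, 0.0])]
        a = np.deg2rad(180.0 - _A_N_CA_C)
        C = [CA[0] + _B_CA_C * np.array([np.cos(a), np.sin(a), 0.0])]
        for i in range(1, len(angles)):
            phi_i = angles[i][0]
            psi_prev = angles[i - 1][1]
            N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N,
                                np.deg2rad(_A_CA_C_N), np.deg2rad(psi_prev)))
            CA.append(place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA,
                                 np.deg2rad(_A_C_N_CA), np.pi))  # omega = 180
            C.append(place_atom(C[i - 1], N[i], CA[i], _B_CA_C,
                                np.deg2rad(_A_N_CA_C), np.deg2rad(phi_i)))
        return N, CA, C

    if conformation in _PHI_PSI:
        angles = [_PHI_PSI[conformation]] * nres
        N, CA, C = backbone_for(angles)
    else:
        # grow residue by residue with clash rejection against earlier CAs
        angles = [draw()]
        N, CA, C = backbone_for(angles)
        for i in range(1, nres):
            chosen = None
            for _ in range(40):
                cand = angles + [draw()]
                Nn, CAn, Cn = backbone_for(cand)
                chosen = (cand, Nn, CAn, Cn)  # last attempt is the fallback
                if i < 2:
                    break
                prev_atoms = np.asarray(N[: i - 1] + CA[: i - 1] + C[: i - 1])
                new_atoms = np.asarray([Nn[i], CAn[i], Cn[i]])
                d = np.linalg.norm(prev_atoms[:, None, :] - new_atoms[None, :, :],
                                   axis=2).min()
                d_ca = np.linalg.norm(np.asarray(CAn[: i - 1]) - CAn[i], axis=1).min()
                if d >= 3.0 and d_ca >= 4.2:
                    break
            angles, N, CA, C = chosen

    psi_last = angles[-1][1] if conformation == "coil" else _PHI_PSI[conformation][1]

    atom_names, atom_res, coords = [], [], []
    for i in range(nres):
        res3 = ONE_TO_THREE[seq[i]]
        atom_names.append("N")
        atom_res.append(i)
        coords.append(N[i])
        if res3 != "PRO":
            if i == 0:
                h = place_atom(C[0], CA[0], N[0], _B_N_H, np.deg2rad(109.5), np.pi)
            else:
                h = amide_h_position(N[i], CA[i], C[i - 1])
            atom_names.append("H")
            atom_res.append(i)
            coords.append(h)
        atom_names.append("CA")
        atom_res.append(i)
        coords.append(CA[i])
        atom_names.append("C")
        atom_res.append(i)
        coords.append(C[i])
        if i + 1 < nres:
            o = place_atom(N[i + 1], CA[i], C[i], _B_C_O,
                           np.deg2rad(_A_CA_C_O), np.pi)
        else:
            o = place_atom(N[i], CA[i], C[i], _B_C_O, np.deg2rad(_A_CA_C_O),
                           np.deg2rad(psi_last + 180.0))
        atom_names.append("O")
        atom_res.append(i)
        coords.append(o)
        if seq[i] != "G":
            cb = place_atom(C[i], N[i], CA[i], _B_CA_CB,
                            np.deg2rad(_A_N_CA_CB), np.deg2rad(-122.6))
            atom_names.append("CB")
            atom_res.append(i)
            coords.append(cb)

    s = Structure(
        chain_id="A",
        res_names=[ONE_TO_THREE[c] for c in seq],
        atom_names=atom_names,
        atom_res=np.asarray(atom_res, dtype=np.int32),
        coords=np.asarray(coords, dtype=float),
    )
    s.validate()
    return s


def make_sequence_pair() -> tuple[str, str]:
    """Length-matched 20-mers for the aggregation-contrast experiment:
    a highly hydrophilic sequence (D/E/K/S/Q, negative mean hydropathy,
    low aggregation propensity) and a very hydrophobic one (L/V/F/I/A,
    positive mean hydropathy, high aggregation propensity)."""
    return "SQDEKSQDEKSQDEKSQDEK", "LVFIALVFIALVFIALVFIA"


def make_synthetic_trace(pattern, dt_ps: float = 10.0) -> DistanceTrace:
    """Build a distance trace from (duration_ps, distance) segments;
    a (duration, d_start, d_end) segment ramps linearly."""
    times, values = [], []
    t = 0.0
    for seg in pattern:
        if len(seg) == 2:
            dur, d0 = seg
            d1 = d0
        else:
            dur, d0, d1 = seg
        n = max(int(round(dur / dt_ps)), 1)
        for k in range(n):
            t += dt_ps
            frac = k / max(n - 1, 1)
            times.append(t)
            values.append(d0 + frac * (d1 - d0))
    return DistanceTrace(times=np.asarray(times), values=np.asarray(values))
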