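"""Ready-made study workflows: the standard experiments the toolkit is
built around, used by the examples, the test suite and the acceptance
script.

* aggregation contrast — two-copy solutions of a very hydrophobic and a
  matched very hydrophilic 20-mer: the hydrophobic pair associates and
  stays bound, the hydrophilic one collides and dissociates.
* unfolding — a helical fixture melted into a coil by the "unfolding"
  parametrisation (hydrophilic force field, weak hydrogen bonds).
* structure-based stability — the same helix held near its reference
  structure by native-contact (Go) wells under the default force field.
"""

from __future__ import annotations

import numpy as np

from .dynamics import Simulation, SimulationConfig, minimize
from .fixtures import make_polypeptide, make_sequence_pair
from .force_field import ForceFieldParams, preset
from .io_formats import Trajectory
from .model_builder import (apply_native_contacts, box_side_from_concentration,
                            build_pacsab_model, extract_native_contacts,
                            replicate_with_offset)

# a soluble, uniformly hydrophilic helix fixture (S/E/K): melted by the
# unfolding parametrisation it expands into a coil instead of collapsing
HELIX_FIXTURE_SEQUENCE = "SESKSESKSESKSESK"


def pair_solution_system(sequence: str, concentration_mM: float = 10.0,
                         structure_seed: int = 11,
                         params: ForceFieldParams | None = None,
                         contact_offset: bool = True):
    """Two random-coil copies of ``sequence`` in a box sized from the
    concentration, steric clashes relaxed away. With ``contact_offset``
    the copy starts 21 A away along x — a surface separation of ~4.5 A,
    in contact from the outset, so only the binding behaviour (transient
    vs irreversible) distinguishes sequences."""
    p = params or preset("default")
    L = box_side_from_concentration(concentration_mM)
    structure = make_polypeptide(sequence, "coil", seed=structure_seed)
    single = build_pacsab_model(structure, p)
    offset = (21.0, 0.0, 0.0) if contact_offset else None
    system = replicate_with_offset(single, offset=offset, L=L)
    return minimize(system, p, use_go=False)


def helix_system(sequence: str = HELIX_FIXTURE_SEQUENCE, box_L: float = 150.0,
                 with_go: bool = False, go_cutoff: float = 8.0,
                 params: ForceFieldParams | None = None):
    """A single ideal helix in a large box, optionally restrained by
    native-contact wells extracted from its own (reference) structure."""
    p = params or preset("default")
    structure = make_polypeptide(sequence, "helix")
    model = build_pacsab_model(structure, p)
    if with_go:
        contacts = extract_native_contacts(structure, cutoff=go_cutoff)
        model = apply_native_contacts(model, contacts)
    return model.with_box(box_L)


def simulate(system, duration_ns: float, seed: int,
             params: ForceFieldParams | None = None, tf_ps: float = 10.0,
             use_go: bool = False, temperature_K: float = 300.0) -> Trajectory:
    """Run ``duration_ns`` of Langevin dynamics at the production
    timestep (10 fs), saving one frame per ``tf_ps``."""
    n_frames = int(round(duration_ns * 1000.0 / tf_ps))
    cfg = SimulationConfig(
        tf_ps=tf_ps, n_frames=n_frames, dt_ps=0.01,
        temperature_K=temperature_K, seed=seed,
        params=params or preset("default"), use_go=use_go)
    return Simulation(system, cfg).run()
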