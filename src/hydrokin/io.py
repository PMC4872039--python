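"""PDB reading and writing for systems and trajectories.

Multi-model PDB is the native trajectory exchange format (lowest common
denominator; every frame shares the topology of MODEL 1). Parsing and
serialisation are delegated to biotite's PDB codec; this module only maps
between biotite's ``AtomArray`` and the package data model.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import MolecularSystem, Trajectory, classify_record

__all__ = ["read_structure", "read_trajectory", "write_structure", "write_trajectory"]


def _infer_element(atom_name: str) -> str:
    """Element from an atom name when the element column is blank."""
    stripped = atom_name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():  # e.g. 1HB
        stripped = stripped.lstrip("0123456789")
    two = stripped[:2].upper()
    if two in {"NA", "CL", "MG", "FE", "ZN", "BR", "SE"}:
        return two
    return stripped[0].upper()


def _atomarray_to_system(arr: struc.AtomArray) -> MolecularSystem:
    elements = np.asarray(arr.element)
    names = np.asarray(arr.atom_name)
    elements = np.array(
        [el if el.strip() else _infer_element(nm) for el, nm in zip(elements, names)]
    )
    resnames = np.asarray(arr.res_name)
    record = np.array([classify_record(rn) for rn in resnames])
    return MolecularSystem(
        names=names,
        elements=elements,
        resids=np.asarray(arr.res_id, dtype=int),
        resnames=resnames,
        chains=np.asarray(arr.chain_id),
        record=record,
        coords=np.asarray(arr.coord, dtype=float),
    )


def _system_to_atomarray(system: MolecularSystem) -> struc.AtomArray:
    n = system.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(system.coords, dtype=np.float32)
    arr.chain_id = np.asarray(system.chains, dtype="U4")
    arr.res_id = np.asarray(system.resids, dtype=int)
    arr.res_name = np.asarray(system.resnames, dtype="U5")
    arr.atom_name = np.asarray(system.names, dtype="U6")
    # PDB element column is upper-case, right-justified; one- or two-letter.
    arr.element = np.array([str(e).strip().upper() for e in system.elements], dtype="U2")
    arr.hetero = np.asarray(system.record) != "protein"
    return arr


def read_structure(path) -> MolecularSystem:
    """Read a PDB file's first model into a :class:`MolecularSystem`.

    Waters (HOH/WAT/TIP3/...) and monatomic ions are classified by residue
    name; everything else is ``protein``.
    """
    pdb = PDBFile.read(str(path))
    if pdb.get_model_count() == 0:
        raise ValueError(f"PDB file {path} contains no ATOM/HETATM records")
    try:
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # malformed records
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise ValueError(f"PDB file {path} contains no ATOM/HETATM records")
    return _atomarray_to_system(arr)


def read_trajectory(path, dt: float | None = None, times=None) -> Trajectory:
    """Read a multi-model PDB file as a trajectory.

    Timestamps come from ``times`` (explicit, ps) or from ``dt`` (uniform
    spacing starting at 0 ps); default dt is 1 ps, the cadence at which
    production trajectories are typically saved.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack over all models
    if stack.array_length() == 0:
        raise ValueError(f"PDB file {path} contains no ATOM/HETATM records")
    n_frames = stack.stack_depth()
    topology = _atomarray_to_system(stack[0])
    frames = np.asarray(stack.coord, dtype=float)
    if times is None:
        step = 1.0 if dt is None else float(dt)
        times = np.arange(n_frames) * step
    times = np.asarray(times, dtype=float)
    if len(times) != n_frames:
        raise ValueError(f"{len(times)} timestamps for {n_frames} frames")
    return Trajectory(topology=topology, frames=frames, times=times)


def write_structure(system: MolecularSystem, path) -> None:
    """Write a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_system_to_atomarray(system))
    pdb.write(str(path))


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a multi-model PDB file (one MODEL per frame).

    PDB stores no timestamps; readers must re-supply ``dt``/``times``.
    """
    template = _system_to_atomarray(trajectory.topology)
    stack = struc.stack([template] * trajectory.n_frames)
    stack.coord = np.asarray(trajectory.frames, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
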