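"""Core data model: molecular systems, trajectories and atom selections.

Coordinates are ångström throughout; times are picoseconds. There is no unit
conversion layer. Residue numbering is taken verbatim from the input; all
residue-list defaults elsewhere in the package assume crystal numbering of
the structure they refer to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MolecularSystem",
    "Trajectory",
    "AtomSelection",
    "ELECTRON_COUNTS",
    "VDW_RADII",
    "BACKBONE_ATOMS",
    "WATER_RESNAMES",
    "ION_RESNAMES",
]

#: Atomic numbers (= electron counts for neutral atoms) for the elements a
#: solvated protein system can contain.
ELECTRON_COUNTS: dict[str, int] = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12, "P": 15,
    "S": 16, "CL": 17, "K": 19, "CA": 20, "FE": 26, "ZN": 30, "SE": 34,
    "BR": 35, "I": 53,
}

#: Van der Waals radii in Å (Bondi 1964, with Rowland & Taylor H).
VDW_RADII: dict[str, float] = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "NA": 2.27,
    "MG": 1.73, "P": 1.80, "S": 1.80, "CL": 1.75, "K": 2.75, "CA": 2.31,
    "FE": 2.00, "ZN": 1.39, "SE": 1.90, "BR": 1.85, "I": 1.98,
}

#: Backbone atom names excluded when a per-residue statistic is "side chain".
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"})

WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL", "H2O"})
ION_RESNAMES = frozenset({"NA", "CL", "SOD", "CLA", "K", "MG", "CA2", "ZN"})


def classify_record(resname: str) -> str:
    """Classify a residue name as ``protein``, ``water`` or ``ion``."""
    rn = resname.strip().upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    return "protein"


@dataclass
class MolecularSystem:
    """A topology plus one coordinate set.

    Parameters
    ----------
    names, elements, resids, resnames, chains, record
        Per-atom annotation arrays of equal length. ``record`` is one of
        ``protein`` / ``water`` / ``ion``.
    coords
        ``(n_atoms, 3)`` float array, Å.
    domains
        Optional per-atom rigid-domain labels (e.g. ``"N"`` / ``"C"``);
        empty string means unassigned. Used by the synthetic hinge generator.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    record: np.ndarray
    coords: np.ndarray
    domains: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.names)
        for arr_name in ("elements", "resids", "resnames", "chains", "record"):
            if len(getattr(self, arr_name)) != n:
                raise ValueError(f"annotation array {arr_name!r} length != atom count")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinate array shape {self.coords.shape} does not match "
                f"{n} atoms"
            )
        if self.domains is not None and len(self.domains) != n:
            raise ValueError("domains length != atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def electrons(self) -> np.ndarray:
        """Electron count per atom; raises on unresolvable elements."""
        out = np.empty(self.n_atoms, dtype=np.int64)
        for i, el in enumerate(self.elements):
            key = str(el).strip().upper()
            if key not in ELECTRON_COUNTS:
                raise ValueError(f"element {el!r} of atom {i} has no electron count")
            out[i] = ELECTRON_COUNTS[key]
        return out

    def vdw_radii(self) -> np.ndarray:
        """Van der Waals radius per atom (Å); raises on unknown elements."""
        out = np.empty(self.n_atoms, dtype=float)
        for i, el in enumerate(self.elements):
            key = str(el).strip().upper()
            if key not in VDW_RADII:
                raise ValueError(
                    f"no van der Waals radius for element {el!r} (atom index {i}, "
                    f"name {self.names[i]!r})"
                )
            out[i] = VDW_RADII[key]
        return out

    def with_coords(self, coords: np.ndarray) -> "MolecularSystem":
        """Same topology with a different coordinate set."""
        return replace(self, coords=np.asarray(coords, dtype=float))

    def subset(self, indices: np.ndarray) -> "MolecularSystem":
        """New system restricted to ``indices`` (kept in given order)."""
        idx = np.asarray(indices)
        return MolecularSystem(
            names=np.asarray(self.names)[idx],
            elements=np.asarray(self.elements)[idx],
            resids=np.asarray(self.resids)[idx],
            resnames=np.asarray(self.resnames)[idx],
            chains=np.asarray(self.chains)[idx],
            record=np.asarray(self.record)[idx],
            coords=self.coords[idx],
            domains=None if self.domains is None else np.asarray(self.domains)[idx],
        )


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing one topology.

    ``frames`` is ``(n_frames, n_atoms, 3)`` in Å, ``times`` strictly
    increasing in ps.
    """

    topology: MolecularSystem
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology atom "
                f"count {self.topology.n_atoms}"
            )
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("times length != frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, i: int) -> MolecularSystem:
        """The i-th frame as a :class:`MolecularSystem`."""
        return self.topology.with_coords(self.frames[i])

    def window(self, t_start: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        """Frame indices and times with ``t_start <= t <= t_end``."""
        mask = (self.times >= t_start) & (self.times <= t_end)
        return np.nonzero(mask)[0], self.times[mask]


def _as_set(value) -> set | None:
    if value is None:
        return None
    if isinstance(value, (str, int, np.integer)):
        return {value}
    return set(value)


@dataclass(frozen=True)
class AtomSelection:
    """A resolved, sorted, duplicate-free list of atom indices."""

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __or__(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(np.union1d(self.indices, other.indices))

    def __and__(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(np.intersect1d(self.indices, other.indices))

    def __sub__(self, other: "AtomSelection") -> "AtomSelection":
        return AtomSelection(np.setdiff1d(self.indices, other.indices))

    @staticmethod
    def select(
        system: MolecularSystem,
        *,
        chain=None,
        resid=None,
        resid_ranges: Sequence[tuple[int, int]] | None = None,
        resname=None,
        name=None,
        record=None,
        domain=None,
    ) -> "AtomSelection":
        """Select atoms by annotation; all given criteria are ANDed.

        ``resid_ranges`` is a list of inclusive ``(lo, hi)`` residue-number
        ranges (the usual way the field writes selections such as
        "Cα of residues 27–44, 51–75, ...").
        """
        mask = np.ones(system.n_atoms, dtype=bool)
        for value, arr in (
            (chain, system.chains),
            (resname, system.resnames),
            (name, system.names),
            (record, system.record),
        ):
            wanted = _as_set(value)
            if wanted is not None:
                mask &= np.isin(np.asarray(arr), list(wanted))
        wanted_resid = _as_set(resid)
        if wanted_resid is not None:
            mask &= np.isin(np.asarray(system.resids), list(wanted_resid))
        if resid_ranges is not None:
            rid = np.asarray(system.resids)
            range_mask = np.zeros(system.n_atoms, dtype=bool)
            for lo, hi in resid_ranges:
                range_mask |= (rid >= lo) & (rid <= hi)
            mask &= range_mask
        if domain is not None:
            if system.domains is None:
                raise ValueError("system has no domain labels")
            mask &= np.isin(np.asarray(system.domains), list(_as_set(domain)))
        return AtomSelection(np.nonzero(mask)[0])
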