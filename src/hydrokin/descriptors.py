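"""Per-residue packing and hydration statistics, and the two site gauges.

R^ASA and R^WAT quantify, residue by residue, how side-chain solvent
exposure and hydration-water count change between the open- and
closed-cleft ensembles: R_i = (⟨X_i⟩_closed − ⟨X_i⟩_open)/⟨X_i⟩_open, so a
negative value means the residue packs (or dehydrates) on closure. Residues
buried in the open ensemble (⟨ASA⟩_open < 10 Å²) are excluded.

The two geometric gauges track the sites the R maps single out: d_HS1 is
the jaw separation of the hydrophobic pocket (ring hydrogen of the
upper-jaw phenylalanine to the midpoint of the two lower-jaw tryptophan
ring atoms); d_HS2 is the stretch of the hydrophilic crevice (alanine Cα to
glutamate Oε1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure as struc

from .core import BACKBONE_ATOMS, AtomSelection, MolecularSystem, Trajectory

__all__ = [
    "compute_asa",
    "count_hydration_waters",
    "residue_change_table",
    "gauge_d_hs1",
    "gauge_d_hs2",
    "gauge_series",
]


def _protein_mask(system: MolecularSystem) -> np.ndarray:
    return np.asarray(system.record) == "protein"


def _sidechain_mask(system: MolecularSystem) -> np.ndarray:
    return _protein_mask(system) & ~np.isin(np.asarray(system.names), list(BACKBONE_ATOMS))


def compute_asa(
    system: MolecularSystem,
    probe_radius: float = 1.4,
    point_number: int = 960,
    per: str = "sidechain",
) -> pd.DataFrame:
    """Per-residue solvent-accessible surface area (Å²).

    Shrake-Rupley sampling (Fibonacci sphere points) with the package's
    van der Waals radii; waters and ions are removed before the calculation,
    protein hydrogens (if present) participate. ``per`` is ``sidechain``
    (backbone N/Cα/C/O and their hydrogens excluded from the per-residue
    sum) or ``residue``.

    Returns a DataFrame with columns chain, resid, resname, asa.
    """
    if per not in ("sidechain", "residue"):
        raise ValueError(f"per must be 'sidechain' or 'residue', got {per!r}")
    prot_idx = np.nonzero(_protein_mask(system))[0]
    if len(prot_idx) == 0:
        raise ValueError("system contains no protein atoms")
    prot = system.subset(prot_idx)
    radii = prot.vdw_radii()  # raises with the offending atom on unknown elements

    arr = struc.AtomArray(prot.n_atoms)
    arr.coord = np.asarray(prot.coords, dtype=np.float32)
    arr.chain_id = np.asarray(prot.chains, dtype="U4")
    arr.res_id = np.asarray(prot.resids, dtype=int)
    arr.res_name = np.asarray(prot.resnames, dtype="U5")
    arr.atom_name = np.asarray(prot.names, dtype="U6")
    arr.element = np.array([str(e).strip().upper() for e in prot.elements], dtype="U2")
    per_atom = struc.sasa(
        arr,
        probe_radius=probe_radius,
        point_number=point_number,
        vdw_radii=radii,
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom)

    if per == "sidechain":
        contribute = ~np.isin(np.asarray(prot.names), list(BACKBONE_ATOMS))
    else:
        contribute = np.ones(prot.n_atoms, dtype=bool)
    df = pd.DataFrame(
        {
            "chain": np.asarray(prot.chains),
            "resid": np.asarray(prot.resids),
            "resname": np.asarray(prot.resnames),
            "asa": np.where(contribute, per_atom, 0.0),
        }
    )
    out = (
        df.groupby(["chain", "resid"], sort=True)
        .agg(resname=("resname", "first"), asa=("asa", "sum"))
        .reset_index()
    )
    return out


def count_hydration_waters(
    system: MolecularSystem,
    resid: int,
    chain: str | None = None,
    cutoff: float = 3.5,
) -> int:
    """Number of distinct water molecules whose oxygen lies within ``cutoff``
    Å of any side-chain atom of the residue.

    The water oxygen is the molecule's counted atom, so hydrogen-less inputs
    behave identically; a water close to several side-chain atoms counts
    once. Residues without side-chain atoms (glycine) give 0 with a warning.
    """
    mask = _sidechain_mask(system) & (np.asarray(system.resids) == resid)
    if chain is not None:
        mask &= np.asarray(system.chains) == chain
    side = system.coords[mask]
    if len(side) == 0:
        warnings.warn(
            f"residue {resid} has no side-chain atoms; hydration count is 0",
            stacklevel=2,
        )
        return 0
    water_o = (np.asarray(system.record) == "water") & (
        np.char.startswith(np.asarray(system.names, dtype="U6"), "O")
    )
    if not water_o.any():
        return 0
    tree = cKDTree(system.coords[water_o])
    hits: set[int] = set()
    for neighbours in tree.query_ball_point(side, cutoff):
        hits.update(neighbours)
    return len(hits)


def residue_change_table(
    trajectory: Trajectory,
    classifications: np.ndarray,
    burial_cutoff: float = 10.0,
    hydration_cutoff: float = 3.5,
    probe_radius: float = 1.4,
    point_number: int = 960,
    mode: str = "relative",
) -> pd.DataFrame:
    """Open→closed change statistics per residue.

    ``classifications`` labels each frame open/closed/intermediate (from the
    first-PC projection); ensemble means use open and closed frames only.
    ``mode="relative"`` gives R = (⟨closed⟩ − ⟨open⟩)/⟨open⟩;
    ``mode="absolute"`` gives the plain difference. Residues with
    ⟨ASA⟩_open below ``burial_cutoff`` are flagged excluded and carry no R
    values (NaN); a residue never hydrated in the open ensemble likewise has
    no finite relative R_wat. Frame order does not matter.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError(f"mode must be 'relative' or 'absolute', got {mode!r}")
    labels = np.asarray(classifications)
    if len(labels) != trajectory.n_frames:
        raise ValueError("one classification label per frame required")
    open_idx = np.nonzero(labels == "open")[0]
    closed_idx = np.nonzero(labels == "closed")[0]
    if len(open_idx) == 0 or len(closed_idx) == 0:
        raise ValueError(
            f"need >= 1 open and >= 1 closed frame "
            f"(got {len(open_idx)} open, {len(closed_idx)} closed)"
        )

    top = trajectory.topology
    prot_res = pd.DataFrame(
        {
            "chain": np.asarray(top.chains)[_protein_mask(top)],
            "resid": np.asarray(top.resids)[_protein_mask(top)],
        }
    ).drop_duplicates().sort_values(["chain", "resid"])
    residues = list(prot_res.itertuples(index=False, name=None))

    def ensemble_means(frame_indices: np.ndarray):
        asa_acc = None
        wat_acc = np.zeros(len(residues))
        for fi in frame_indices:
            frame = trajectory.frame(int(fi))
            asa = compute_asa(frame, probe_radius, point_number).set_index(["chain", "resid"])["asa"]
            asa_acc = asa if asa_acc is None else asa_acc + asa
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wat_acc += [
                    count_hydration_waters(frame, resid, chain, hydration_cutoff)
                    for chain, resid in residues
                ]
        return asa_acc / len(frame_indices), wat_acc / len(frame_indices)

    asa_open, wat_open = ensemble_means(open_idx)
    asa_closed, wat_closed = ensemble_means(closed_idx)

    index = pd.MultiIndex.from_tuples(residues, names=["chain", "resid"])
    table = pd.DataFrame(
        {
            "asa_open": asa_open.reindex(index).to_numpy(),
            "asa_closed": asa_closed.reindex(index).to_numpy(),
            "wat_open": wat_open,
            "wat_closed": wat_closed,
        },
        index=index,
    )
    table["excluded"] = table["asa_open"] < burial_cutoff
    if mode == "relative":
        with np.errstate(divide="ignore", invalid="ignore"):
            r_asa = (table["asa_closed"] - table["asa_open"]) / table["asa_open"]
            r_wat = (table["wat_closed"] - table["wat_open"]) / table["wat_open"]
        r_wat = r_wat.replace([np.inf, -np.inf], np.nan)
    else:
        r_asa = table["asa_closed"] - table["asa_open"]
        r_wat = table["wat_closed"] - table["wat_open"]
    table["r_asa"] = r_asa.where(~table["excluded"])
    table["r_wat"] = r_wat.where(~table["excluded"])
    return table.reset_index()


# ---------------------------------------------------------------------------
# Site gauges

def _find_atoms(system: MolecularSystem, resid: int, names: list[str], chain=None) -> np.ndarray:
    mask = (np.asarray(system.resids) == resid) & np.isin(np.asarray(system.names), names)
    if chain is not None:
        mask &= np.asarray(system.chains) == chain
    return np.nonzero(mask)[0]


def gauge_d_hs1(
    system: MolecularSystem,
    res_upper: int = 340,
    res_lower_a: int = 89,
    res_lower_b: int = 92,
    chain: str | None = None,
) -> float:
    """Jaw separation of the hydrophobic pocket (Å).

    Minimum over the upper-jaw ring hydrogens (Hδ1, Hε1 — chemically
    equivalent ring positions) of the distance to the midpoint of the
    lower-jaw Cδ1 (first tryptophan) and Cγ (second tryptophan). Requires
    hydrogens; errors if they are absent.
    """
    h_idx = _find_atoms(system, res_upper, ["HD1", "HE1"], chain)
    if len(h_idx) == 0:
        raise ValueError(
            f"residue {res_upper} has no HD1/HE1 ring hydrogen: the jaw gauge "
            "requires a structure with hydrogens"
        )
    cd1 = _find_atoms(system, res_lower_a, ["CD1"], chain)
    cg = _find_atoms(system, res_lower_b, ["CG"], chain)
    if len(cd1) == 0 or len(cg) == 0:
        missing = f"{res_lower_a}:CD1" if len(cd1) == 0 else f"{res_lower_b}:CG"
        raise ValueError(f"lower-jaw atom {missing} not found")
    midpoint = 0.5 * (system.coords[cd1[0]] + system.coords[cg[0]])
    d = float(np.min(np.linalg.norm(system.coords[h_idx] - midpoint, axis=1)))
    if d == 0.0:
        warnings.warn("jaw atom groups coincide; d_HS1 is degenerate (0 Å)", stacklevel=2)
    return d


def gauge_d_hs2(
    system: MolecularSystem,
    res_ca: int = 190,
    res_oe1: int = 354,
    chain: str | None = None,
) -> float:
    """Crevice stretch (Å): alanine Cα to glutamate Oε1 distance."""
    ca = _find_atoms(system, res_ca, ["CA"], chain)
    oe1 = _find_atoms(system, res_oe1, ["OE1"], chain)
    if len(ca) == 0:
        raise ValueError(f"atom {res_ca}:CA not found")
    if len(oe1) == 0:
        raise ValueError(f"atom {res_oe1}:OE1 not found")
    return float(np.linalg.norm(system.coords[ca[0]] - system.coords[oe1[0]]))


@dataclass
class GaugeSeries:
    """Time series of the two site gauges, aligned with the trajectory."""

    times: np.ndarray
    d_hs1: np.ndarray
    d_hs2: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "d_hs1": self.d_hs1, "d_hs2": self.d_hs2})


def gauge_series(trajectory: Trajectory, chain: str | None = None, **kwargs) -> GaugeSeries:
    """d_HS1 and d_HS2 for every frame."""
    hs1_kw = {k: v for k, v in kwargs.items() if k in ("res_upper", "res_lower_a", "res_lower_b")}
    hs2_kw = {k: v for k, v in kwargs.items() if k in ("res_ca", "res_oe1")}
    d1 = np.array([gauge_d_hs1(trajectory.frame(i), chain=chain, **hs1_kw) for i in range(trajectory.n_frames)])
    d2 = np.array([gauge_d_hs2(trajectory.frame(i), chain=chain, **hs2_kw) for i in range(trajectory.n_frames)])
    return GaugeSeries(times=trajectory.times.copy(), d_hs1=d1, d_hs2=d2)


__all__.append("GaugeSeries")
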