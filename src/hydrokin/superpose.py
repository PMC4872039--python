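"""Rigid-body (Kabsch) superposition.

The returned transform is fitted on a subset of atoms and applicable to any
coordinate set of the same frame — superposing on one domain and applying
the transform to the whole system (protein plus solvent) is the basic move
behind both the domain PCA and the windowed solvent density maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "kabsch_superpose"]


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R @ (x − mobile_center) + target_center."""

    rotation: np.ndarray  # (3, 3), proper: det = +1
    mobile_center: np.ndarray
    target_center: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return (coords - self.mobile_center) @ self.rotation.T + self.target_center

    @property
    def translation(self) -> np.ndarray:
        """Net translation t such that x ↦ R x + t."""
        return self.target_center - self.rotation @ self.mobile_center

    @staticmethod
    def identity() -> "RigidTransform":
        zero = np.zeros(3)
        return RigidTransform(np.eye(3), zero, zero)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference
        ``(n, 3)`` coordinate arrays of the same atom count.
    fit_indices
        Atom indices the fit minimises over (default: all). The transform
        may afterwards be applied to any subset of the mobile frame.

    Returns
    -------
    (transform, rmsd)
        Proper rotation (det = +1) plus translation, and the RMSD (Å) over
        the fit atoms after superposition.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    if fit_indices is None:
        m, r = mobile, reference
    else:
        idx = np.asarray(fit_indices)
        m, r = mobile[idx], reference[idx]
    if len(m) < 3:
        raise ValueError(f"need >= 3 fit atoms, got {len(m)}")
    m_center = m.mean(axis=0)
    r_center = r.mean(axis=0)
    m0 = m - m_center
    # Collinear fit sets leave a free rotation about the line: reject them.
    if np.linalg.matrix_rank(m0, tol=1e-8 * max(1.0, np.abs(m0).max())) < 2:
        raise ValueError("fit atoms are collinear; superposition is degenerate")
    rot, _ = Rotation.align_vectors(r - r_center, m0)
    transform = RigidTransform(rot.as_matrix(), m_center, r_center)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(m) - r) ** 2, axis=1))))
    return transform, rmsd
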