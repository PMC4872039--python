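"""Principal component analysis of rigid-body domain motion.

The protocol uses two distinct atom sets: a *fit* set (the static domain,
used only for superposition) and an *analysis* set (the moving domain's
rigid core, whose Cartesian covariance is eigendecomposed). Projections on
the leading component are in Å and serve as the collective open/close
coordinate of the inter-domain cleft; by convention positive projection =
more open. A simplified screw-axis (Chasles) decomposition between the two
extreme conformations stands in for a full dynamic-domain segmentation when
the hinge axis is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import AtomSelection, MolecularSystem, Trajectory
from .superpose import kabsch_superpose

__all__ = [
    "PCAModel",
    "ScrewAxis",
    "fit_pca",
    "project",
    "project_many",
    "axis_correlation",
    "hinge_axis",
    "classify_conformation",
    "classify_projections",
]


@dataclass
class PCAModel:
    """Domain-motion PCA model.

    components are orthonormal row vectors in the 3·M-dimensional space of
    the analysis set; variances are in Å² and non-increasing.
    """

    fit_selection: AtomSelection
    analysis_selection: AtomSelection
    reference_coords: np.ndarray  # full reference frame, for superposition
    mean_coords: np.ndarray  # (M, 3) mean of superposed analysis set
    components: np.ndarray  # (k, 3M)
    variances: np.ndarray  # (k,)

    @property
    def fractions(self) -> np.ndarray:
        return self.variances / self.variances.sum()


def _superposed_analysis_coords(
    frames: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray, ana_idx: np.ndarray
) -> np.ndarray:
    out = np.empty((len(frames), len(ana_idx), 3))
    for i, frame in enumerate(frames):
        transform, _ = kabsch_superpose(frame, reference, fit_idx)
        out[i] = transform.apply(frame[ana_idx])
    return out


def _opening_gauge(frames_superposed_analysis: np.ndarray, reference: np.ndarray,
                   fit_idx: np.ndarray) -> np.ndarray:
    """Cleft-opening proxy per conformation: distance between the analysis
    set centroid and the (static) fit-set centroid of the reference."""
    fit_centroid = reference[fit_idx].mean(axis=0)
    centroids = frames_superposed_analysis.mean(axis=1)
    return np.linalg.norm(centroids - fit_centroid, axis=1)


def fit_pca(
    conformations: Trajectory | np.ndarray,
    fit_selection: AtomSelection,
    analysis_selection: AtomSelection,
    n_components: int | None = None,
    opening_gauge: np.ndarray | None = None,
) -> PCAModel:
    """Fit the domain-motion PCA.

    Every conformation is superposed on the first via the fit selection, the
    covariance of the analysis-set Cartesian coordinates (normalised by
    n − 1) is eigendecomposed, and each component's sign is fixed so that
    projection correlates positively with cleft opening: pass a
    per-conformation opening measure (ideally the pocket jaw distance
    d_HS1) as ``opening_gauge``; without one, the distance between the
    analysis-set and fit-set centroids serves as a geometric proxy for how
    far the domains have swung apart.
    """
    frames = conformations.frames if isinstance(conformations, Trajectory) else np.asarray(conformations, dtype=float)
    if frames.ndim != 3:
        raise ValueError("conformations must be an (n, n_atoms, 3) array or Trajectory")
    n = len(frames)
    if n < 2:
        raise ValueError(f"need >= 2 conformations, got {n}")
    fit_idx = fit_selection.indices
    ana_idx = analysis_selection.indices
    if len(ana_idx) == 0:
        raise ValueError("empty analysis selection")
    reference = frames[0]
    coords = _superposed_analysis_coords(frames, reference, fit_idx, ana_idx)
    flat = coords.reshape(n, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    components = eigvecs[:, order].T  # rows
    if n_components is not None:
        eigvals = eigvals[:n_components]
        components = components[:n_components]
    # Sign convention: positive projection = wider cleft. Correlate each
    # component's projections with the opening gauge; fall back to a fixed
    # lexicographic rule when the gauge carries no signal.
    if opening_gauge is not None:
        gauge = np.asarray(opening_gauge, dtype=float)
        if len(gauge) != n:
            raise ValueError("opening_gauge must give one value per conformation")
    else:
        gauge = _opening_gauge(coords, reference, fit_idx)
    projections = centered @ components.T
    for k in range(len(components)):
        g = gauge - gauge.mean()
        corr = float(projections[:, k] @ g)
        if abs(corr) > 1e-12:
            if corr < 0:
                components[k] = -components[k]
        else:
            nz = np.nonzero(np.abs(components[k]) > 1e-12)[0]
            if len(nz) and components[k][nz[0]] < 0:
                components[k] = -components[k]
    return PCAModel(
        fit_selection=fit_selection,
        analysis_selection=analysis_selection,
        reference_coords=reference.copy(),
        mean_coords=mean.reshape(-1, 3),
        components=components,
        variances=eigvals,
    )


def project(model: PCAModel, conformation: np.ndarray | MolecularSystem) -> np.ndarray:
    """Per-component projections (Å) of one conformation."""
    coords = conformation.coords if isinstance(conformation, MolecularSystem) else np.asarray(conformation, dtype=float)
    if coords.shape != model.reference_coords.shape:
        raise ValueError(
            f"conformation shape {coords.shape} incompatible with model "
            f"reference {model.reference_coords.shape}"
        )
    transform, _ = kabsch_superpose(coords, model.reference_coords, model.fit_selection.indices)
    ana = transform.apply(coords[model.analysis_selection.indices])
    centered = ana.reshape(-1) - model.mean_coords.reshape(-1)
    return model.components @ centered


def project_many(model: PCAModel, conformations: Trajectory | np.ndarray) -> np.ndarray:
    """(n, k) projections for a trajectory or coordinate stack."""
    frames = conformations.frames if isinstance(conformations, Trajectory) else np.asarray(conformations, dtype=float)
    return np.stack([project(model, f) for f in frames])


def axis_correlation(model_a: PCAModel, model_b: PCAModel, component: int = 0) -> float:
    """Absolute cosine between the two models' component vectors."""
    if len(model_a.analysis_selection) != len(model_b.analysis_selection):
        raise ValueError("models have different analysis-set sizes")
    va = model_a.components[component]
    vb = model_b.components[component]
    return float(abs(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))


@dataclass(frozen=True)
class ScrewAxis:
    """Chasles decomposition of a rigid motion: rotation by ``angle``
    (degrees, in (0, 180]) about the line through ``point`` along unit
    ``direction``, plus ``translation`` (Å) along that line."""

    direction: np.ndarray
    point: np.ndarray
    angle: float
    translation: float


def hinge_axis(
    conformation_open: np.ndarray,
    conformation_closed: np.ndarray,
    fit_selection: AtomSelection,
    moving_selection: AtomSelection,
    min_angle: float = 1.0,
) -> ScrewAxis:
    """Screw axis of the moving domain between two conformations.

    The closed conformation is first superposed on the open one via the fit
    selection (removing overall motion of the static domain); the remaining
    best rigid transform of the moving selection is decomposed into screw
    parameters. This is a simplified single-pair decomposition, not a
    dynamic-domain clustering.
    """
    open_c = np.asarray(conformation_open, dtype=float)
    closed_c = np.asarray(conformation_closed, dtype=float)
    align, _ = kabsch_superpose(closed_c, open_c, fit_selection.indices)
    closed_aligned = align.apply(closed_c)
    move, _ = kabsch_superpose(
        open_c[moving_selection.indices], closed_aligned[moving_selection.indices]
    )
    R = move.rotation
    t = move.translation
    rotvec = Rotation.from_matrix(R).as_rotvec()
    angle = float(np.degrees(np.linalg.norm(rotvec)))
    if angle < min_angle:
        raise ValueError(
            f"rotation angle {angle:.3g} deg below {min_angle} deg: screw axis "
            "ill-conditioned (motion is essentially a pure translation)"
        )
    direction = rotvec / np.linalg.norm(rotvec)
    t_parallel = float(t @ direction)
    # point on axis: (I - R) p = t_perp; min-norm least-squares solution
    t_perp = t - t_parallel * direction
    p, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return ScrewAxis(direction=direction, point=p, angle=angle, translation=t_parallel)


def classify_conformation(
    projection: float, open_threshold: float = 15.0, closed_threshold: float = -15.0
) -> str:
    """open / closed / intermediate from the first-component projection (Å)."""
    if projection > open_threshold:
        return "open"
    if projection < closed_threshold:
        return "closed"
    return "intermediate"


def classify_projections(
    projections, open_threshold: float = 15.0, closed_threshold: float = -15.0
) -> np.ndarray:
    p = np.asarray(projections, dtype=float)
    out = np.full(p.shape, "intermediate", dtype="U12")
    out[p > open_threshold] = "open"
    out[p < closed_threshold] = "closed"
    return out
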