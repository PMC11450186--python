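"""Connectome geometry: projected synapse-cloud area and column span.

A transmedullary neuron's axis is estimated as the leading principal
component of its presynaptic-site point cloud; partner synapse clouds are
projected onto the plane spanned by the remaining two components, where the
convex-hull area (um^2) and the maximal pairwise extent — normalized by the
11.2 um medulla-column pitch to give a column span — are measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .errors import DegenerateGeometryError, InvalidSpecError

__all__ = [
    "SynapseCloud",
    "ProjectionPlane",
    "HullMetrics",
    "COLUMN_PITCH_UM",
    "projection_plane",
    "hull_metrics",
]

#: Average diameter of a single medulla column in the EM volume (um).
COLUMN_PITCH_UM = 11.2


@dataclass
class SynapseCloud:
    """3-D synapse coordinates (um) with optional partner labels."""

    points: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 3:
            raise InvalidSpecError("points must be an (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise InvalidSpecError("coordinates must be finite")

    @classmethod
    def from_csv(cls, path) -> "SynapseCloud":
        import pandas as pd

        df = pd.read_csv(path)
        pts = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
        labels = df["label"].to_numpy() if "label" in df else None
        return cls(points=pts, labels=labels)


@dataclass
class ProjectionPlane:
    """Principal axis and the orthonormal basis of its perpendicular plane."""

    axis: np.ndarray
    basis: np.ndarray  # (2, 3), rows orthonormal
    centroid: np.ndarray

    def project(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64)) - self.centroid
        return pts @ self.basis.T


def projection_plane(reference_cloud: SynapseCloud) -> ProjectionPlane:
    """PCA of the centered cloud: axis = leading eigenvector, plane = rest.

    Sign convention: each basis vector is flipped so its largest-magnitude
    component is positive, and the axis so its z-component (or, if zero, its
    first nonzero component) is positive, making the basis reproducible.
    """
    pts = reference_cloud.points
    if len(pts) < 3:
        raise DegenerateGeometryError("need at least three points")
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] <= 1e-12 * max(evals[0], 1.0):
        raise DegenerateGeometryError("point cloud is (near-)collinear")

    def canonical(v: np.ndarray) -> np.ndarray:
        i = int(np.argmax(np.abs(v)))
        return v if v[i] > 0 else -v

    axis = evecs[:, 0]
    if axis[2] != 0:
        axis = axis if axis[2] > 0 else -axis
    else:
        axis = canonical(axis)
    basis = np.vstack([canonical(evecs[:, 1]), canonical(evecs[:, 2])])
    return ProjectionPlane(axis=axis, basis=basis, centroid=centroid)


@dataclass
class HullMetrics:
    area: float  # um^2
    max_extent: float  # um
    column_span: float  # multiples of the column pitch
    n_points: int


def hull_metrics(
    partner_cloud: SynapseCloud,
    plane: ProjectionPlane,
    column_pitch: float = COLUMN_PITCH_UM,
) -> HullMetrics:
    """Convex-hull area and column span of the projected partner cloud.

    The span uses the largest pairwise distance over all projected points
    (identical to using hull vertices) divided by the column pitch.
    """
    proj = plane.project(partner_cloud.points)
    if len(proj) < 2:
        raise DegenerateGeometryError("need at least two points for a span")
    max_extent = float(pdist(proj).max())
    if len(proj) < 3:
        raise DegenerateGeometryError("need at least three points for an area")
    try:
        area = float(ConvexHull(proj).volume)  # 2-D hull: volume == area
    except Exception as exc:  # collinear projections
        raise DegenerateGeometryError(f"degenerate projected cloud: {exc}") from exc
    return HullMetrics(
        area=area,
        max_extent=max_extent,
        column_span=max_extent / column_pitch,
        n_points=len(proj),
    )
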