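"""Tetrahedral (tetrachromatic) colour space.

Relative single-cone catches are mapped into a regular tetrahedron whose
centroid is the origin (equal stimulation of all four cones) and whose
vertices — each at distance 0.75 from the origin — correspond to exclusive
stimulation of one cone class.  The UV vertex sits on the +z axis; the
orientation is a plotting convention and does not affect distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .visual_model import SINGLE_CONES, QuantumCatchVector

__all__ = [
    "VERTEX_DISTANCE",
    "VERTICES",
    "RelativeCatch",
    "TetraPoint",
    "relative_catches",
    "tetra_coordinates",
    "colourspace_distance",
    "plot_tetra",
]

VERTEX_DISTANCE = 0.75

# Vertex per cone, order (UV, SW, MW, LW): UV on +z, the other three on the
# z = -0.25 plane at radius sqrt(0.5), 120 degrees apart.  Vertices sum to
# zero, so the barycentric map sends equal stimulation to the origin.
_r = np.sqrt(VERTEX_DISTANCE**2 - 0.25**2)
_angles = np.deg2rad([90.0, 210.0, 330.0])
VERTICES = np.array(
    [[0.0, 0.0, VERTEX_DISTANCE]]
    + [[_r * np.cos(a), _r * np.sin(a), -0.25] for a in _angles]
)


@dataclass(frozen=True)
class RelativeCatch:
    """Proportions of total single-cone catch (u + s + m + l = 1)."""

    u: float
    s: float
    m: float
    l: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"relative catches outside [0, 1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"relative catches must sum to 1, got {arr.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.s, self.m, self.l])


@dataclass(frozen=True)
class TetraPoint:
    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


def relative_catches(q: QuantumCatchVector) -> RelativeCatch:
    """Normalise the four single-cone catches to proportions of their sum."""
    arr = q.single_cone_array()
    if np.any(arr < 0):
        raise ValueError("negative quantum catch")
    total = arr.sum()
    if total <= 0:
        raise ValueError("zero total catch: cannot form relative catches")
    u, s, m, l = arr / total
    return RelativeCatch(u, s, m, l)


def tetra_coordinates(rc: RelativeCatch) -> TetraPoint:
    """Affine barycentric map from the catch simplex into the tetrahedron."""
    xyz = rc.as_array() @ VERTICES
    return TetraPoint(*map(float, xyz))


def colourspace_distance(p1: TetraPoint, p2: TetraPoint) -> float:
    """Euclidean distance between two colour-space points."""
    return float(np.linalg.norm(p1.as_array() - p2.as_array()))


def plot_tetra(points: dict[str, TetraPoint], path=None, elev: float = 10.0,
               azim: float = -60.0):
    """3-D scatter of colour-space points with the tetrahedron wireframe.

    Returns the matplotlib figure; saves to ``path`` (PNG/SVG) if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    for i in range(4):
        for j in range(i + 1, 4):
            seg = VERTICES[[i, j]]
            ax.plot(seg[:, 0], seg[:, 1], seg[:, 2], c="0.7", lw=0.8)
    for cone, v in zip(SINGLE_CONES, VERTICES):
        ax.text(*v * 1.08, cone, ha="center")
    for label, p in points.items():
        ax.scatter(p.x, p.y, p.z, label=label, s=25)
    if len(points) <= 12:
        ax.legend(fontsize=7)
    ax.view_init(elev=elev, azim=azim)
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
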