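"""Under-ischium soft-tissue metrics: cylinder ROIs, thickness, volume reduction.

Sustained seated load compresses the gluteal soft tissue between the
ischial tuberosity (IT) and the cushion.  The compression is quantified
inside two cylindrical regions of interest (20 mm and 50 mm diameter),
axis perpendicular to the seat-pan plane, positioned at the ischium point
closest to the seat.  Inside each ROI we report the mean tissue thickness
along the axis and the tissue volume, and from a pre/post-loading mesh
pair the volume reduction

    R = (1 - V_loaded / V_preload) * 100  [%].

Both thickness and volume come from the same axis-parallel ray grid cast
over the cylinder cross-section: each ray's chord length inside the tissue
elements is its local thickness, and volume is chord length times ray-cell
area summed over rays.  This makes the two metrics mutually consistent
(V = mean thickness x hit area) and robust on hexahedral meshes; accuracy
is controlled by the grid spacing.  Hexahedra are decomposed into six
tetrahedra for the ray intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .vtkio import read_vtk, write_vtk

DEFAULT_RAY_GRID_MM = 0.5
DEFAULT_ROI_HEIGHT_MM = 200.0

# 6-tet decomposition of a VTK hexahedron along the 0-6 diagonal
_HEX_TO_TETS = np.array(
    [[0, 1, 2, 6], [0, 2, 3, 6], [0, 3, 7, 6], [0, 7, 4, 6], [0, 4, 5, 6], [0, 5, 1, 6]]
)


@dataclass
class SoftTissueMesh:
    """Volumetric tissue mesh (mm): nodes plus hex and/or tet connectivity.

    The volumetric elements ARE the tissue: a chord's tissue membership is
    its intersection with the element union (bone is not meshed, so bone
    cavities are naturally excluded).  Optional cell data (e.g. skin/bone
    facet tags from upstream tools) is carried through I/O untouched.
    """

    nodes: np.ndarray
    hexes: np.ndarray = field(default_factory=lambda: np.zeros((0, 8), dtype=int))
    tets: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=int))
    cell_data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.hexes = np.asarray(self.hexes, dtype=int).reshape(-1, 8)
        self.tets = np.asarray(self.tets, dtype=int).reshape(-1, 4)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.n_cells == 0:
            raise ValueError("mesh has no volumetric cells")

    @property
    def n_cells(self) -> int:
        return len(self.hexes) + len(self.tets)

    def tet_soup(self) -> np.ndarray:
        """All elements as tetrahedra, (T, 4, 3) vertex coordinates."""
        parts = []
        if len(self.hexes):
            parts.append(self.nodes[self.hexes[:, _HEX_TO_TETS]].reshape(-1, 4, 3))
        if len(self.tets):
            parts.append(self.nodes[self.tets])
        return np.concatenate(parts, axis=0)

    def transformed(self, rotation: np.ndarray | None = None, translation=0.0) -> "SoftTissueMesh":
        nodes = self.nodes
        if rotation is not None:
            nodes = nodes @ np.asarray(rotation, dtype=float).T
        nodes = nodes + np.asarray(translation, dtype=float)
        return SoftTissueMesh(nodes, self.hexes.copy(), self.tets.copy(), dict(self.cell_data))

    @classmethod
    def load(cls, path: str | Path) -> "SoftTissueMesh":
        nodes, hexes, tets, cell_data = read_vtk(path)
        return cls(nodes=nodes, hexes=hexes, tets=tets, cell_data=cell_data)

    def save(self, path: str | Path, title: str = "soft tissue mesh") -> None:
        write_vtk(path, self.nodes, self.hexes, self.tets, self.cell_data or None, title)


@dataclass(frozen=True)
class CylinderROI:
    """Cylindrical ROI under the IT.

    ``apex`` is the ischium point closest to the seat; ``axis`` the unit
    seat-pan normal pointing from the seat toward the body.  The cylinder's
    upper face plane contains the apex (so its rim circle touches the
    ischium) and the body extends ``height_mm`` seat-ward along -axis.
    """

    apex: np.ndarray
    axis: np.ndarray
    diameter_mm: float
    height_mm: float = DEFAULT_ROI_HEIGHT_MM

    def __post_init__(self) -> None:
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        if self.diameter_mm <= 0 or self.height_mm <= 0:
            raise ValueError("diameter and height must be positive")
        if not np.isclose(np.linalg.norm(self.axis), 1.0, atol=1e-9):
            raise ValueError("axis must be a unit vector")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def basis(self) -> np.ndarray:
        """Orthonormal frame (u, v, axis) as rows; u, v span the cross-section."""
        w = self.axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(w @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(ref, w)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        return np.vstack([u, v, w])

    def rim_points(self, n: int = 16) -> np.ndarray:
        """Points on the upper rim circle (in the apex plane, radius d/2)."""
        u, v, _ = self.basis()
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return self.apex + self.radius_mm * (np.outer(np.cos(th), u) + np.outer(np.sin(th), v))


@dataclass(frozen=True)
class TissueROIStats:
    t_mean_mm: float
    v_mm3: float
    n_rays_hit: int


def build_roi(
    ischium_point,
    seat_normal,
    diameter_mm: float,
    height_mm: float = DEFAULT_ROI_HEIGHT_MM,
) -> CylinderROI:
    """Construct the ROI cylinder from the IT landmark and seat-pan normal."""
    normal = np.asarray(seat_normal, dtype=float)
    n = np.linalg.norm(normal)
    if n == 0:
        raise ValueError("seat normal must be nonzero")
    return CylinderROI(
        apex=np.asarray(ischium_point, dtype=float),
        axis=normal / n,
        diameter_mm=diameter_mm,
        height_mm=height_mm,
    )


# ---------------------------------------------------------------------------
# Ray casting


def _merge_length(enter: np.ndarray, exit_: np.ndarray) -> float:
    """Total length of the union of intervals (enter_i, exit_i)."""
    order = np.argsort(enter)
    total = 0.0
    cur_a, cur_b = None, None
    for a, b in zip(enter[order], exit_[order]):
        if cur_b is None:
            cur_a, cur_b = a, b
        elif a <= cur_b + 1e-9:
            cur_b = max(cur_b, b)
        else:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
    if cur_b is not None:
        total += cur_b - cur_a
    return total


class _RayCaster:
    """Casts axis-parallel rays through a tet soup expressed in the ROI frame.

    The ROI frame has the cylinder axis along +z and the apex at the
    origin; rays are vertical lines, so each tet face plane n.x = c yields
    a linear bound on the ray parameter and the inside interval comes from
    max/min over the four faces.  Tets are bucketed on a coarse 2-D grid by
    their (x, y) bounding box to keep the per-ray candidate set small.
    """

    def __init__(self, mesh: SoftTissueMesh, roi: CylinderROI):
        B = roi.basis()  # rows u, v, w
        verts = (mesh.tet_soup() - roi.apex) @ B.T  # (T, 4, 3) in ROI frame
        v0 = verts[:, 0]
        # outward face normals: face k is opposite vertex k
        faces = [(1, 2, 3, 0), (0, 3, 2, 1), (0, 1, 3, 2), (0, 2, 1, 3)]
        normals = np.empty((len(verts), 4, 3))
        offsets = np.empty((len(verts), 4))
        for k, (i, j, l, m) in enumerate(faces):
            n = np.cross(verts[:, j] - verts[:, i], verts[:, l] - verts[:, i])
            inward = np.einsum("ij,ij->i", n, verts[:, m] - verts[:, i])
            n = np.where(inward[:, None] > 0, -n, n)  # orient outward
            normals[:, k] = n
            offsets[:, k] = np.einsum("ij,ij->i", n, verts[:, i])
        self.normals = normals
        self.offsets = offsets
        lo = verts[..., :2].min(axis=1)
        hi = verts[..., :2].max(axis=1)
        self.cell = max(2.0, float(np.median(hi[:, 0] - lo[:, 0])))
        self.origin2d = lo.min(axis=0) - 1e-9
        ij_lo = np.floor((lo - self.origin2d) / self.cell).astype(int)
        ij_hi = np.floor((hi - self.origin2d) / self.cell).astype(int)
        self.buckets: dict[tuple[int, int], list[int]] = {}
        for t in range(len(verts)):
            for ix in range(ij_lo[t, 0], ij_hi[t, 0] + 1):
                for iy in range(ij_lo[t, 1], ij_hi[t, 1] + 1):
                    self.buckets.setdefault((ix, iy), []).append(t)
        self.buckets = {k: np.array(v) for k, v in self.buckets.items()}

    def chord(self, x: float, y: float, z_lo: float, z_hi: float) -> float:
        """Chord length of the vertical line at (x, y) inside the tissue,
        clipped to z in [z_lo, z_hi]."""
        key = (
            int(np.floor((x - self.origin2d[0]) / self.cell)),
            int(np.floor((y - self.origin2d[1]) / self.cell)),
        )
        cand = self.buckets.get(key)
        if cand is None:
            return 0.0
        n = self.normals[cand]  # (C, 4, 3)
        c = self.offsets[cand]
        b = c - n[..., 0] * x - n[..., 1] * y  # n.x <= c along ray z: nz*z <= b
        nz = n[..., 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            upper = np.where(nz > 0, b / nz, np.inf)
            lower = np.where(nz < 0, b / nz, -np.inf)
        infeasible = (nz == 0) & (b < 0)
        t_in = np.maximum(lower.max(axis=1), z_lo)
        t_out = np.minimum(upper.min(axis=1), z_hi)
        t_out = np.where(infeasible.any(axis=1), -np.inf, t_out)
        ok = t_out > t_in + 1e-12
        if not ok.any():
            return 0.0
        return _merge_length(t_in[ok], t_out[ok])


def _ray_stats(
    mesh: SoftTissueMesh, roi: CylinderROI, ray_grid_mm: float
) -> tuple[np.ndarray, int]:
    """Chord lengths for all rays of the ROI cross-section grid."""
    if ray_grid_mm <= 0:
        raise ValueError("ray_grid_mm must be positive")
    caster = _RayCaster(mesh, roi)
    r = roi.radius_mm
    # ray centers on a symmetric square grid covering the circle
    n_half = int(np.ceil(r / ray_grid_mm))
    coords = (np.arange(-n_half, n_half + 1) + 0.0) * ray_grid_mm
    xs, ys = np.meshgrid(coords, coords, indexing="ij")
    inside = xs**2 + ys**2 <= r**2
    chords = np.array(
        [caster.chord(x, y, -roi.height_mm, 0.0) for x, y in zip(xs[inside], ys[inside])]
    )
    return chords, int(inside.sum())


def mean_thickness(
    mesh: SoftTissueMesh, roi: CylinderROI, ray_grid_mm: float = DEFAULT_RAY_GRID_MM
) -> float:
    """Mean tissue thickness along the ROI axis, averaged over hitting rays."""
    chords, _ = _ray_stats(mesh, roi, ray_grid_mm)
    hit = chords > 0
    if not hit.any():
        return float("nan")
    return float(chords[hit].mean())


def roi_volume(
    mesh: SoftTissueMesh, roi: CylinderROI, ray_grid_mm: float = DEFAULT_RAY_GRID_MM
) -> float:
    """Tissue volume inside the ROI cylinder (mm^3), chord-sum quadrature."""
    chords, _ = _ray_stats(mesh, roi, ray_grid_mm)
    return float(chords.sum() * ray_grid_mm**2)


def roi_stats(
    mesh: SoftTissueMesh, roi: CylinderROI, ray_grid_mm: float = DEFAULT_RAY_GRID_MM
) -> TissueROIStats:
    """Thickness and volume from a single ray sweep (mutually consistent)."""
    chords, _ = _ray_stats(mesh, roi, ray_grid_mm)
    hit = chords > 0
    n_hit = int(hit.sum())
    t_mean = float(chords[hit].mean()) if n_hit else float("nan")
    return TissueROIStats(
        t_mean_mm=t_mean, v_mm3=float(chords.sum() * ray_grid_mm**2), n_rays_hit=n_hit
    )


def volume_reduction(
    pre: SoftTissueMesh,
    post: SoftTissueMesh,
    roi: CylinderROI,
    ray_grid_mm: float = DEFAULT_RAY_GRID_MM,
) -> float:
    """R = (1 - V_loaded/V_preload) * 100, the ROI tissue volume reduction.

    The same ROI (seat frame) is applied to both states.
    """
    v_pre = roi_volume(pre, roi, ray_grid_mm)
    if v_pre <= 0:
        raise ValueError("pre-loading mesh has no tissue inside the ROI")
    v_post = roi_volume(post, roi, ray_grid_mm)
    return (1.0 - v_post / v_pre) * 100.0


# ---------------------------------------------------------------------------
# Structured-block factory (fixtures and the synthetic generator build on it)


def make_box_mesh(
    origin=(0.0, 0.0, 0.0),
    size=(100.0, 100.0, 40.0),
    spacing_mm: float = 5.0,
) -> SoftTissueMesh:
    """Axis-aligned hexahedral block mesh with ~uniform element size."""
    origin = np.asarray(origin, dtype=float)
    size = np.asarray(size, dtype=float)
    counts = np.maximum(1, np.round(size / spacing_mm).astype(int))
    axes = [np.linspace(origin[k], origin[k] + size[k], counts[k] + 1) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    nx, ny, nz = counts
    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k
    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append(
                    [
                        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                    ]
                )
    return SoftTissueMesh(nodes=nodes, hexes=np.array(hexes, dtype=int))
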