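"""Boundary-element forward solver for nested triangulated head surfaces.

A collocation BEM with piecewise-constant potential per triangle: for a
piecewise-homogeneous conductor bounded by closed nested surfaces, the
surface potential satisfies the classical double-layer integral equation

    (s_in + s_out)/2 V(r) = s0 v0(r)
        + (1/4pi) sum_m (s_in_m - s_out_m) int_{S_m} V(r') dOmega_r'(r)

where v0 is the infinite-medium dipole potential at the source conductivity
s0 and dOmega is the solid-angle element (positive from interior points).
Solid angles of triangles are computed with the van Oosterom-Strackee
formula; each observation row is corrected so that the discrete solid angle
of the observation point's own surface totals 2 pi.  The additive-constant
null space that appears because no current leaves the head is removed by
deflation, and gain columns are returned in a zero-channel-mean convention
(noted in the leadfield provenance).

Canonical spherical meshes (for validating against the analytic concentric
sphere solution) are generated with trimesh icospheres.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .exceptions import ValidationError
from .forward import HeadModel, Leadfield, SourceGrid
from .montage import Montage

__all__ = [
    "make_bem_sphere_model",
    "bem_leadfield",
    "read_mesh",
    "write_mesh",
]


def make_bem_sphere_model(
    scalp_radius_mm: float = 92.0,
    radii_rel: tuple[float, float, float] = (0.87, 0.92, 1.0),
    conductivities: tuple[float, float, float] = (1.0, 0.0125, 1.0),
    subdivisions: int = 3,
) -> HeadModel:
    """Three nested icosphere meshes matching the concentric-sphere model."""
    meshes = []
    for rel in radii_rel:
        m = trimesh.creation.icosphere(
            subdivisions=subdivisions, radius=rel * scalp_radius_mm
        )
        meshes.append((np.asarray(m.vertices), np.asarray(m.faces)))
    return HeadModel(
        "bem3", radii_rel, conductivities, scalp_radius_mm, meshes=tuple(meshes)
    )


def _validate_meshes(model: HeadModel) -> list[trimesh.Trimesh]:
    out = []
    for li, (verts, faces) in enumerate(model.meshes):
        m = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        if not m.is_watertight:
            raise ValidationError(f"layer {li}: mesh is not closed (watertight)")
        if not m.is_winding_consistent:
            raise ValidationError(f"layer {li}: inconsistent triangle orientation")
        if m.volume < 0:
            m.invert()
        out.append(m)
    # nesting: each surface must lie strictly inside the next one out
    # (winding number via summed solid angles: ~4 pi from interior points)
    for li in range(len(out) - 1):
        inner_pts = np.asarray(out[li].vertices)
        outer = out[li + 1]
        total = _solid_angles(
            inner_pts, np.asarray(outer.vertices), np.asarray(outer.faces)
        ).sum(axis=1)
        if not np.all(total > 2.0 * np.pi):
            raise ValidationError(f"layer {li} mesh is not nested inside layer {li + 1}")
    return out


def _solid_angles(obs: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Solid angle (van Oosterom-Strackee) of each triangle from each point.

    Positive for observation points on the interior side of an outward-
    oriented closed surface.  Shape: (n_obs, n_faces).
    """
    tri = vertices[faces]  # (F, 3, 3)
    out = np.empty((obs.shape[0], faces.shape[0]))
    chunk = max(1, int(4e6 // max(faces.shape[0], 1)))
    for start in range(0, obs.shape[0], chunk):
        p = obs[start : start + chunk]  # (C, 3)
        r = tri[None, :, :, :] - p[:, None, None, :]  # (C, F, 3, 3)
        r1, r2, r3 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        n1 = np.linalg.norm(r1, axis=-1)
        n2 = np.linalg.norm(r2, axis=-1)
        n3 = np.linalg.norm(r3, axis=-1)
        numer = np.einsum("cfi,cfi->cf", r1, np.cross(r2, r3))
        denom = (
            n1 * n2 * n3
            + np.einsum("cfi,cfi->cf", r1, r2) * n3
            + np.einsum("cfi,cfi->cf", r1, r3) * n2
            + np.einsum("cfi,cfi->cf", r2, r3) * n1
        )
        out[start : start + chunk] = 2.0 * np.arctan2(numer, denom)
    return out


def _infinite_medium_potential(
    points: np.ndarray, source_pos: np.ndarray, sigma0: float
) -> np.ndarray:
    """sigma0 * v0 for unit dipoles along x/y/z: shape (n_points, 3)."""
    d = points - source_pos[None, :]
    dn3 = np.linalg.norm(d, axis=1) ** 3
    return d / (4.0 * np.pi * dn3[:, None])


class _BemSystem:
    """Factored BEM system for one head model."""

    def __init__(self, model: HeadModel):
        meshes = _validate_meshes(model)
        self.model = model
        self.centroids = np.vstack([m.triangles_center for m in meshes])
        self.areas = np.concatenate([m.area_faces for m in meshes])
        self.surface_of = np.concatenate(
            [np.full(len(m.faces), li) for li, m in enumerate(meshes)]
        )
        self.meshes = meshes
        n_layers = len(meshes)
        conds = model.conductivities
        sigma_in = np.array(conds)
        sigma_out = np.array(list(conds[1:]) + [0.0])
        self.sigma_in, self.sigma_out = sigma_in, sigma_out

        omega_blocks = []
        for m in meshes:
            omega_blocks.append(_solid_angles(self.centroids, np.asarray(m.vertices), np.asarray(m.faces)))
        omega = np.hstack(omega_blocks)  # (n_tri, n_tri)
        # own-surface auto solid angle: rows must total 2*pi over the own surface
        for li in range(n_layers):
            cols = self.surface_of == li
            rows = np.flatnonzero(cols)
            row_sums = omega[np.ix_(rows, np.flatnonzero(cols))].sum(axis=1)
            omega[rows, rows] += 2.0 * np.pi - row_sums
        dsig = (sigma_in - sigma_out)[self.surface_of]  # per column
        mu = 0.5 * (sigma_in + sigma_out)[self.surface_of]  # per row
        a = np.diag(mu) - omega * (dsig[None, :] / (4.0 * np.pi))
        # deflation of the additive-constant null space (area-weighted mean -> 0)
        w = self.areas / self.areas.sum()
        a += np.mean(mu) * np.outer(np.ones(len(w)), w)
        self.lu = None
        import scipy.linalg as sla

        self.lu = sla.lu_factor(a)
        self._sla = sla

    def solve_surface(self, rhs: np.ndarray) -> np.ndarray:
        return self._sla.lu_solve(self.lu, rhs)

    def electrode_operator(self, montage: Montage) -> tuple[np.ndarray, np.ndarray, float]:
        """Evaluation points just inside the outer surface plus the
        interior-representation weights for those points."""
        outer = self.meshes[-1]
        # pull electrodes radially inside the outer polyhedron so the
        # interior representation (conductivity = scalp) applies smoothly
        centre = outer.triangles_center.mean(axis=0)
        min_centroid_r = np.linalg.norm(outer.triangles_center - centre, axis=1).min()
        pos = montage.positions
        units = (pos - centre) / np.linalg.norm(pos - centre, axis=1, keepdims=True)
        eval_pts = centre + units * (0.995 * min_centroid_r)
        blocks = [
            _solid_angles(eval_pts, np.asarray(m.vertices), np.asarray(m.faces))
            for m in self.meshes
        ]
        omega_e = np.hstack(blocks)
        dsig = (self.sigma_in - self.sigma_out)[self.surface_of]
        weights = omega_e * (dsig[None, :] / (4.0 * np.pi))
        sigma_scalp = self.model.conductivities[-1]
        return eval_pts, weights, sigma_scalp


def bem_leadfield(model: HeadModel, montage: Montage, grid: SourceGrid) -> Leadfield:
    """Gain matrix of grid dipoles through a triangulated head model."""
    if model.kind != "bem3":
        raise ValidationError("bem_leadfield requires a bem3 model")
    system = _BemSystem(model)
    sigma0 = model.conductivities[0]
    pos = grid.positions
    n_tri = system.centroids.shape[0]
    rhs = np.empty((n_tri, 3 * pos.shape[0]))
    for j in range(pos.shape[0]):
        rhs[:, 3 * j : 3 * j + 3] = _infinite_medium_potential(
            system.centroids, pos[j], sigma0
        )
    u = system.solve_surface(rhs)
    eval_pts, weights, sigma_scalp = system.electrode_operator(montage)
    gain = np.empty((montage.n_channels, 3 * pos.shape[0]))
    for j in range(pos.shape[0]):
        b_e = _infinite_medium_potential(eval_pts, pos[j], sigma0)
        gain[:, 3 * j : 3 * j + 3] = (
            b_e + weights @ u[:, 3 * j : 3 * j + 3]
        ) / sigma_scalp
    gain -= gain.mean(axis=0, keepdims=True)
    return Leadfield(
        gain=gain,
        channel_labels=tuple(montage.labels),
        montage_ref=montage.name or f"montage(N={montage.n_channels})",
        grid_ref=f"grid(spacing={grid.spacing_mm:g}mm, M={grid.n_sources})",
        model_ref=model.describe() + "; BEM constant-collocation; zero-mean columns",
    )


# ---------------------------------------------------------------------------
# ASCII triangle mesh I/O: "nv nf" header, vertex lines (mm), 0-based faces


def write_mesh(vertices: np.ndarray, faces: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(vertices)} {len(faces)}\n")
        for v in vertices:
            fh.write(f"{v[0]:.8f} {v[1]:.8f} {v[2]:.8f}\n")
        for f in faces:
            fh.write(f"{f[0]} {f[1]} {f[2]}\n")


def read_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValidationError(f"{path}: expected 'n_vertices n_faces' header")
        nv, nf = int(header[0]), int(header[1])
        verts = np.array(
            [[float(x) for x in fh.readline().split()] for _ in range(nv)]
        )
        faces = np.array(
            [[int(x) for x in fh.readline().split()] for _ in range(nf)]
        )
    if verts.shape != (nv, 3) or faces.shape != (nf, 3):
        raise ValidationError(f"{path}: malformed mesh file")
    return verts, faces
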