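"""Dipole forward models in layered spherical conductors and leadfields.

This module generates the synthetic scalp potentials that drive every
downstream analysis.  Two analytic head models are provided:

* a homogeneous sphere, with the classical closed-form surface potential of
  an eccentric current dipole;
* a layered concentric-sphere model (brain/skull/scalp), solved as a
  Legendre series with per-degree transfer coefficients obtained from the
  interface continuity conditions (potential and radial current continuous,
  no current through the outer surface).

Potentials are "infinity-referenced": they are the physical potential field
of the conductor, defined up to no additive constant, which is the natural
reference-free representation a re-referencing operator is judged against.
Units: positions in mm, conductivities as relative ratios, dipole moments in
arbitrary units; only potential ratios matter for the error metrics.

A boundary-element model for realistic (or canonical spherical) triangulated
surfaces lives in :mod:`neuroref.bem` and is dispatched to from
:func:`build_leadfield`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, ValidationError
from .montage import Montage

__all__ = [
    "HeadModel",
    "Dipole",
    "SourceGrid",
    "Leadfield",
    "potential_sphere1",
    "potential_sphere3",
    "build_leadfield",
    "make_source_grid",
    "sample_dipoles",
    "read_leadfield",
    "write_leadfield",
]

#: default truncation of the Legendre series; deep dipoles converge much
#: faster, superficial ones (shallower than ~90% of the brain radius) are
#: excluded by the default depth margin and converge well below 1e-8 here
DEFAULT_N_TERMS = 100

#: default depth margin as a fraction of the brain-compartment radius
DEFAULT_DEPTH_MARGIN_FRACTION = 0.1


@dataclass(frozen=True)
class HeadModel:
    """Layered spherical (or triangulated) volume conductor.

    ``radii_rel`` are layer radii relative to the scalp radius, ordered from
    the innermost (brain) outward; ``conductivities`` are the matching layer
    conductivities as ratios (only ratios influence the potential shape).
    """

    kind: str
    radii_rel: tuple[float, ...]
    conductivities: tuple[float, ...]
    scalp_radius_mm: float = 92.0
    meshes: tuple | None = None  # for bem3: ((vertices, faces), ...) innermost first

    def __post_init__(self) -> None:
        if self.kind not in ("sphere1", "sphere3", "bem3"):
            raise ConfigurationError(f"unknown head model kind {self.kind!r}")
        radii = tuple(float(r) for r in self.radii_rel)
        conds = tuple(float(c) for c in self.conductivities)
        if len(radii) != len(conds):
            raise ValidationError("radii and conductivities must have equal length")
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValidationError("layer radii must be strictly increasing")
        if any(c <= 0 for c in conds):
            raise ValidationError("conductivities must be positive")
        if self.scalp_radius_mm <= 0:
            raise ValidationError("scalp radius must be positive")
        if self.kind == "bem3" and (self.meshes is None or len(self.meshes) != len(radii)):
            raise ValidationError("bem3 model needs one mesh per layer")
        object.__setattr__(self, "radii_rel", radii)
        object.__setattr__(self, "conductivities", conds)

    @classmethod
    def sphere1(cls, scalp_radius_mm: float = 92.0, conductivity: float = 1.0) -> "HeadModel":
        return cls("sphere1", (1.0,), (conductivity,), scalp_radius_mm)

    @classmethod
    def sphere3(
        cls,
        scalp_radius_mm: float = 92.0,
        radii_rel: tuple[float, float, float] = (0.87, 0.92, 1.0),
        conductivities: tuple[float, float, float] = (1.0, 0.0125, 1.0),
    ) -> "HeadModel":
        return cls("sphere3", radii_rel, conductivities, scalp_radius_mm)

    @property
    def brain_radius_mm(self) -> float:
        return self.radii_rel[0] * self.scalp_radius_mm

    def describe(self) -> str:
        return (
            f"{self.kind}(R={self.scalp_radius_mm:g}mm, radii={self.radii_rel}, "
            f"cond={self.conductivities})"
        )


@dataclass(frozen=True)
class Dipole:
    """A current dipole: position (mm) and moment (orientation x amplitude)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        mom = np.asarray(self.moment, dtype=float)
        if pos.shape != (3,) or mom.shape != (3,):
            raise ValidationError("dipole position and moment must be 3-vectors")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(mom))):
            raise ValidationError("dipole position/moment must be finite")
        if np.linalg.norm(mom) == 0:
            raise ValidationError("dipole moment must be nonzero")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment", mom)


@dataclass(frozen=True)
class SourceGrid:
    """Ordered dipole locations on a regular lattice inside the brain."""

    positions: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[0] < 1 or pos.shape[1] != 3:
            raise ValidationError("source grid needs at least one 3-D position")
        if not np.all(np.isfinite(pos)):
            raise ValidationError("source grid positions must be finite")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class Leadfield:
    """Gain matrix G of shape (channels, 3*M), voxel-major x/y/z columns."""

    gain: np.ndarray
    channel_labels: tuple[str, ...]
    montage_ref: str = ""
    grid_ref: str = ""
    model_ref: str = ""

    def __post_init__(self) -> None:
        gain = np.asarray(self.gain, dtype=float)
        if gain.ndim != 2 or gain.shape[1] % 3 != 0:
            raise ValidationError("gain must be (N, 3*M)")
        if not np.all(np.isfinite(gain)):
            raise ValidationError("gain contains non-finite entries")
        if len(self.channel_labels) != gain.shape[0]:
            raise ValidationError("channel label count does not match gain rows")
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1] // 3


# ---------------------------------------------------------------------------
# analytic sphere models


def _electrode_units(montage: Montage, model: HeadModel) -> np.ndarray:
    """Electrode unit directions; electrodes are taken on the model scalp."""
    pos = montage.positions
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("electrode at the sphere centre")
    return pos / norms


def _check_inside(position: np.ndarray, model: HeadModel) -> float:
    b = float(np.linalg.norm(position))
    if b >= model.brain_radius_mm:
        raise ValidationError(
            f"dipole at radius {b:.2f} mm is outside the innermost compartment "
            f"({model.brain_radius_mm:.2f} mm)"
        )
    return b


def potential_sphere1(dipole: Dipole, montage: Montage, model: HeadModel) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    For a dipole with moment ``p`` at ``r0`` inside an insulated homogeneous
    sphere of radius R and conductivity sigma, the surface potential at
    electrode ``r_e`` (|r_e| = R) is

        V = [ 2 (d.p)/d^3 + ((r_e + R d/|d|).p) / (R F) ] / (4 pi sigma),

    with d = r_e - r0 and F = R^2 - r0.r_e + R |d|.  This is the closed-form
    sum of the Legendre series and serves as the independent oracle for the
    layered model.
    """
    if model.kind != "sphere1":
        raise ConfigurationError("potential_sphere1 requires a sphere1 model")
    _check_inside(dipole.position, model)
    r = model.scalp_radius_mm
    sigma = model.conductivities[0]
    e = _electrode_units(montage, model) * r
    r0 = dipole.position
    p = dipole.moment
    d = e - r0[None, :]
    dn = np.linalg.norm(d, axis=1)
    f = r * r - e @ r0 + r * dn
    v = 2.0 * (d @ p) / dn**3 + ((e @ p) + r * (d @ p) / dn) / (r * f)
    return v / (4.0 * np.pi * sigma)


def _shell_transfer_coefficients(model: HeadModel, n_terms: int) -> np.ndarray:
    """Per-degree surface transfer coefficients t_n of a layered sphere.

    For each spherical-harmonic degree n, a unit source term r^-(n+1) in the
    innermost layer produces the surface amplitude t_n.  Obtained by solving
    the interface continuity conditions layer by layer (radii scaled to the
    scalp radius).  For a homogeneous sphere t_n = (2n+1)/n.
    """
    radii = np.asarray(model.radii_rel)
    conds = np.asarray(model.conductivities)
    n_layers = len(radii)
    t = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        m = 2 * n_layers - 1  # unknowns: A_1, (A_i, B_i) for i >= 2
        a_mat = np.zeros((m, m))
        rhs = np.zeros(m)

        def col_a(i: int) -> int:  # index of A_i, layers 1-based
            return 0 if i == 1 else 2 * i - 3

        def col_b(i: int) -> int:
            return 2 * i - 2

        row = 0
        for i in range(1, n_layers):  # interface between layer i and i+1 at radii[i-1]
            r = radii[i - 1]
            rp_n = r**n
            rm_n = r ** (-(n + 1))
            # potential continuity
            a_mat[row, col_a(i)] += rp_n
            if i > 1:
                a_mat[row, col_b(i)] += rm_n
            a_mat[row, col_a(i + 1)] -= rp_n
            a_mat[row, col_b(i + 1)] -= rm_n
            if i == 1:
                rhs[row] = -rm_n  # source term lives in layer 1
            row += 1
            # radial current continuity
            dp = n * r ** (n - 1)
            dm = -(n + 1) * r ** (-(n + 2))
            a_mat[row, col_a(i)] += conds[i - 1] * dp
            if i > 1:
                a_mat[row, col_b(i)] += conds[i - 1] * dm
            a_mat[row, col_a(i + 1)] -= conds[i] * dp
            a_mat[row, col_b(i + 1)] -= conds[i] * dm
            if i == 1:
                rhs[row] = -conds[0] * dm
            row += 1
        # no current through the outer surface (radius 1)
        a_mat[row, col_a(n_layers)] += n
        if n_layers > 1:
            a_mat[row, col_b(n_layers)] += -(n + 1)
        else:
            rhs[row] = n + 1  # homogeneous: A_1 * n = (n+1) * source
        if n_layers > 1:
            rhs[row] = 0.0
        sol = np.linalg.solve(a_mat, rhs)
        if n_layers == 1:
            t[n] = 1.0 + sol[0]
        else:
            t[n] = sol[col_a(n_layers)] + sol[col_b(n_layers)]
    return t


def _series_surface_potential(
    e_unit: np.ndarray,
    r0_mm: np.ndarray,
    p: np.ndarray,
    model: HeadModel,
    t_n: np.ndarray,
) -> np.ndarray:
    """Evaluate the Legendre series at unit electrode directions."""
    r_scale = model.scalp_radius_mm
    sigma1 = model.conductivities[0]
    b = np.linalg.norm(r0_mm) / r_scale
    r0_hat = np.array([0.0, 0.0, 1.0]) if b < 1e-12 else r0_mm / np.linalg.norm(r0_mm)
    c = e_unit @ r0_hat
    p_r0 = float(p @ r0_hat)
    p_e = e_unit @ p
    n_terms = len(t_n) - 1
    p_prev = np.ones_like(c)  # P_0
    p_cur = c.copy()  # P_1
    dp_prev = np.zeros_like(c)  # P'_0
    dp_cur = np.ones_like(c)  # P'_1
    bpow = 1.0  # b^(n-1)
    acc = np.zeros_like(c)
    for n in range(1, n_terms + 1):
        acc += t_n[n] * bpow * (n * p_r0 * p_cur + (p_e - c * p_r0) * dp_cur)
        bpow *= b
        p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
    return acc / (4.0 * np.pi * sigma1 * r_scale**2)


def potential_sphere3(
    dipole: Dipole, montage: Montage, model: HeadModel, n_terms: int = DEFAULT_N_TERMS
) -> np.ndarray:
    """Surface potential of a dipole in the concentric-shell sphere model.

    Legendre-series solution truncated at ``n_terms``; reduces to the
    homogeneous closed form when all layer conductivities are equal.
    """
    if model.kind != "sphere3":
        raise ConfigurationError("potential_sphere3 requires a sphere3 model")
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    _check_inside(dipole.position, model)
    t_n = _shell_transfer_coefficients(model, n_terms)
    e_unit = _electrode_units(montage, model)
    return _series_surface_potential(e_unit, dipole.position, dipole.moment, model, t_n)


def _sphere_leadfield(
    model: HeadModel, montage: Montage, grid: SourceGrid, n_terms: int
) -> np.ndarray:
    """Vectorised series evaluation for all grid dipoles and orientations."""
    r_scale = model.scalp_radius_mm
    sigma1 = model.conductivities[0]
    t_n = _shell_transfer_coefficients(model, n_terms)
    e_unit = _electrode_units(montage, model)  # (N, 3)
    pos = grid.positions
    for j in range(pos.shape[0]):
        _check_inside(pos[j], model)
    b = np.linalg.norm(pos, axis=1) / r_scale  # (M,)
    r0_hat = np.where(
        b[:, None] < 1e-12, np.array([0.0, 0.0, 1.0]), pos / np.maximum(np.linalg.norm(pos, axis=1), 1e-300)[:, None]
    )
    c = r0_hat @ e_unit.T  # (M, N)
    n_terms_i = len(t_n) - 1
    p_prev = np.ones_like(c)
    p_cur = c.copy()
    dp_prev = np.zeros_like(c)
    dp_cur = np.ones_like(c)
    bpow = np.ones_like(b)  # b^(n-1)
    acc_a = np.zeros_like(c)  # sum t_n b^(n-1) n P_n
    acc_b = np.zeros_like(c)  # sum t_n b^(n-1) P'_n
    for n in range(1, n_terms_i + 1):
        w = t_n[n] * bpow[:, None]
        acc_a += w * (n * p_cur)
        acc_b += w * dp_cur
        bpow *= b
        p_next = ((2 * n + 1) * c * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
    scale = 1.0 / (4.0 * np.pi * sigma1 * r_scale**2)
    m = pos.shape[0]
    n_ch = e_unit.shape[0]
    gain = np.empty((n_ch, 3 * m))
    for k in range(3):
        # moment = unit vector along axis k:  p.r0_hat = r0_hat[:,k],  p.e = e_unit[:,k]
        v = acc_a * r0_hat[:, k][:, None] + acc_b * (
            e_unit[:, k][None, :] - c * r0_hat[:, k][:, None]
        )
        gain[:, k::3] = scale * v.T
    return gain


def build_leadfield(
    model: HeadModel,
    montage: Montage,
    grid: SourceGrid,
    n_terms: int = DEFAULT_N_TERMS,
) -> Leadfield:
    """Assemble the gain matrix G: column 3*j+k is the scalp map of a unit
    dipole at grid position j oriented along axis k (x, y, z)."""
    if model.kind in ("sphere1", "sphere3"):
        gain = _sphere_leadfield(model, montage, grid, n_terms)
    elif model.kind == "bem3":
        from .bem import bem_leadfield

        return bem_leadfield(model, montage, grid)
    else:  # pragma: no cover - guarded by HeadModel validation
        raise ConfigurationError(f"unsupported model kind {model.kind!r}")
    return Leadfield(
        gain=gain,
        channel_labels=tuple(montage.labels),
        montage_ref=montage.name or f"montage(N={montage.n_channels})",
        grid_ref=f"grid(spacing={grid.spacing_mm:g}mm, M={grid.n_sources})",
        model_ref=model.describe(),
    )


# ---------------------------------------------------------------------------
# source sampling


def _max_source_radius(model: HeadModel, depth_margin_mm: float | None) -> float:
    r_brain = model.brain_radius_mm
    if depth_margin_mm is None:
        depth_margin_mm = DEFAULT_DEPTH_MARGIN_FRACTION * r_brain
    if depth_margin_mm < 0 or depth_margin_mm >= r_brain:
        raise ValidationError(
            f"depth margin {depth_margin_mm:g} mm must lie in [0, {r_brain:g})"
        )
    return r_brain - depth_margin_mm


def make_source_grid(
    model: HeadModel,
    spacing_mm: float = 10.0,
    depth_margin_mm: float | None = None,
) -> SourceGrid:
    """Regular cubic lattice covering the brain compartment."""
    if spacing_mm <= 0:
        raise ValidationError("grid spacing must be positive")
    rmax = _max_source_radius(model, depth_margin_mm)
    k = int(np.floor(rmax / spacing_mm))
    offs = spacing_mm * np.arange(-k, k + 1)
    xx, yy, zz = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= rmax]
    return SourceGrid(positions=pts, spacing_mm=spacing_mm)


def sample_dipoles(
    model: HeadModel,
    n: int,
    seed: int,
    depth_margin_mm: float | None = None,
) -> np.ndarray:
    """n positions drawn uniformly from the brain ball minus the depth margin."""
    if n < 1:
        raise ValidationError("need n >= 1 dipoles")
    rmax = _max_source_radius(model, depth_margin_mm)
    rng = np.random.default_rng(seed)
    directions = rng.standard_normal((n, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii = rmax * rng.uniform(size=n) ** (1.0 / 3.0)
    return directions * radii[:, None]


# ---------------------------------------------------------------------------
# leadfield I/O: delimited matrix + JSON sidecar


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(".json") if p.suffix else Path(str(p) + ".json")


def write_leadfield(leadfield: Leadfield, path) -> None:
    path = Path(path)
    np.savetxt(path, leadfield.gain, fmt="%.17e", delimiter="\t")
    sidecar = {
        "n_channels": leadfield.n_channels,
        "n_sources": leadfield.n_sources,
        "orientation_order": "voxel-major, xyz within voxel",
        "units": "arbitrary (moment units / mm^2)",
        "model": leadfield.model_ref,
        "montage": leadfield.montage_ref,
        "grid": leadfield.grid_ref,
        "channel_labels": list(leadfield.channel_labels),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_leadfield(path) -> Leadfield:
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise ValidationError(
            f"missing sidecar {sidecar_path}; regenerate the leadfield with write_leadfield"
        )
    meta = json.loads(sidecar_path.read_text())
    gain = np.loadtxt(path, delimiter="\t", ndmin=2)
    if gain.shape != (meta["n_channels"], 3 * meta["n_sources"]):
        raise ValidationError(
            f"sidecar declares shape {(meta['n_channels'], 3 * meta['n_sources'])} "
            f"but matrix has shape {gain.shape}"
        )
    return Leadfield(
        gain=gain,
        channel_labels=tuple(meta["channel_labels"]),
        montage_ref=meta.get("montage", ""),
        grid_ref=meta.get("grid", ""),
        model_ref=meta.get("model", ""),
    )
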