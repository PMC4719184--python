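"""Electrode montages: construction, file I/O, perturbation and rigid alignment.

Coordinate convention (used throughout the package): right-handed "head
frame" with the origin at the centre of the scalp sphere, +x toward the
right preauricular point, +y toward the nasion and +z toward the vertex.
All lengths are in millimetres.

Montages are built on an ideal spherical scalp.  The 10/20 and 10/10
layouts follow the classical arc construction of the nomenclature (vertex
at the pole, nasion/inion and the preauricular points on the equator, the
outer 10/20 ring at 72 degrees polar angle).  High-density layouts use a
Fibonacci lattice on a spherical cap, mimicking the coverage of geodesic
sensor nets, with two dedicated mastoid channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, NumericalError, ParseError, ValidationError

__all__ = [
    "Electrode",
    "Montage",
    "HeadShape",
    "make_standard_montage",
    "read_montage",
    "write_montage",
    "perturb_positions",
    "rigid_align",
    "STANDARD_MONTAGES",
]

#: default scalp sphere radius in mm (adult head)
DEFAULT_SCALP_RADIUS_MM = 92.0

#: recognised standard montage names and their channel counts
STANDARD_MONTAGES = {"ten20_21": 21, "ten10_71": 71, "dense_128": 128, "dense_256": 256}

#: polar angle (degrees from vertex) of the lower edge of the dense caps.
#: The 256-channel geodesic net extends further down the head (cheeks and
#: neck) than the 128-channel net, which is what makes average-reference
#: coverage improve between the two.
CAP_ANGLE_DEG = {"dense_128": 115.0, "dense_256": 126.0}

#: canonical mastoid position (polar angle, azimuth) -- just below and
#: slightly behind the ears
_MASTOID_POLAR_DEG = 100.0
_MASTOID_AZIMUTH_DEG = 108.0

_FIDUCIAL_LABELS = ("nasion", "lpa", "rpa")

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class Electrode:
    """A labelled scalp electrode position (mm, head frame)."""

    label: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("electrode label must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValidationError(f"electrode {self.label!r}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"electrode {self.label!r}: non-finite position")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class HeadShape:
    """Digitised scalp/fiducial points used as a rigid-alignment reference."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValidationError("headshape needs at least 3 points of dimension 3")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("headshape contains non-finite points")
        # non-collinearity: the centred point cloud must span at least 2 dims
        centred = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
            raise ValidationError("headshape points are collinear")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class Montage:
    """An ordered set of electrodes with designated Cz and mastoid channels."""

    electrodes: tuple[Electrode, ...]
    scalp_radius_mm: float = DEFAULT_SCALP_RADIUS_MM
    cz_index: int = 0
    left_mastoid_index: int = 1
    right_mastoid_index: int = 2
    fiducials: dict[str, np.ndarray] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "electrodes", tuple(self.electrodes))
        n = len(self.electrodes)
        if n < 3:
            raise ValidationError(f"montage needs at least 3 electrodes, got {n}")
        if self.scalp_radius_mm <= 0:
            raise ValidationError("scalp radius must be positive")
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != n:
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate electrode labels: {dup}")
        idx = (self.cz_index, self.left_mastoid_index, self.right_mastoid_index)
        for i in idx:
            if not (0 <= i < n):
                raise ValidationError(f"designated channel index {i} out of range [0, {n})")
        if len(set(idx)) != 3:
            raise ValidationError("Cz and mastoid indices must be distinct")

    @property
    def n_channels(self) -> int:
        return len(self.electrodes)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of electrode positions in mm."""
        return np.array([e.position for e in self.electrodes])

    def with_positions(self, positions: np.ndarray) -> "Montage":
        """Same labels/designations with replaced positions."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_channels, 3):
            raise ValidationError(
                f"expected positions of shape {(self.n_channels, 3)}, got {positions.shape}"
            )
        electrodes = tuple(
            Electrode(e.label, p) for e, p in zip(self.electrodes, positions)
        )
        return replace(self, electrodes=electrodes)

    def index_of(self, label: str) -> int:
        for i, e in enumerate(self.electrodes):
            if e.label == label:
                return i
        raise KeyError(label)

    def assert_on_sphere(self, tol_mm: float = 0.1) -> None:
        radii = np.linalg.norm(self.positions, axis=1)
        worst = np.abs(radii - self.scalp_radius_mm).max()
        if worst > tol_mm:
            raise ValidationError(
                f"electrodes deviate from the scalp sphere by up to {worst:.3g} mm"
            )


# ---------------------------------------------------------------------------
# geometry helpers


def _sph(polar_deg: float, azimuth_deg: float, radius: float) -> np.ndarray:
    """Point on the scalp sphere.

    ``polar_deg`` is measured from the vertex (+z); ``azimuth_deg`` from the
    nasion direction (+y) increasing toward the right ear (+x).
    """
    th = math.radians(polar_deg)
    ph = math.radians(azimuth_deg)
    return radius * np.array(
        [math.sin(th) * math.sin(ph), math.sin(th) * math.cos(ph), math.cos(th)]
    )


def _slerp(p: np.ndarray, q: np.ndarray, t: float) -> np.ndarray:
    """Great-circle interpolation between two points on a common sphere."""
    r = np.linalg.norm(p)
    u, v = p / r, q / np.linalg.norm(q)
    ang = math.acos(np.clip(np.dot(u, v), -1.0, 1.0))
    if ang < 1e-12:
        return p.copy()
    w = (math.sin((1 - t) * ang) * u + math.sin(t * ang) * v) / math.sin(ang)
    return r * w


def _fibonacci_cap(n: int, cap_angle_deg: float, radius: float) -> np.ndarray:
    """n approximately equal-area points on a spherical cap around +z."""
    z_min = math.cos(math.radians(cap_angle_deg))
    i = np.arange(n)
    z = 1.0 - (i + 0.5) / n * (1.0 - z_min)
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    return radius * np.column_stack([s * np.sin(phi), s * np.cos(phi), z])


def _project_to_sphere(positions: np.ndarray, radius: float) -> np.ndarray:
    norms = np.linalg.norm(positions, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise NumericalError("cannot project a point at the origin onto the scalp")
    return positions * (radius / norms)


# ---------------------------------------------------------------------------
# standard layouts


def _ten20_rows(radius: float) -> list[tuple[str, np.ndarray]]:
    ring = {
        "Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
        "P7": -126, "P8": 126, "O1": -162, "O2": 162,
    }
    pos = {lab: _sph(72, az, radius) for lab, az in ring.items()}
    pos["Fz"] = _sph(36, 0, radius)
    pos["Cz"] = _sph(0, 0, radius)
    pos["Pz"] = _sph(36, 180, radius)
    pos["C3"] = _sph(36, -90, radius)
    pos["C4"] = _sph(36, 90, radius)
    pos["F3"] = _slerp(pos["Fz"], pos["F7"], 0.5)
    pos["F4"] = _slerp(pos["Fz"], pos["F8"], 0.5)
    pos["P3"] = _slerp(pos["Pz"], pos["P7"], 0.5)
    pos["P4"] = _slerp(pos["Pz"], pos["P8"], 0.5)
    pos["M1"] = _sph(_MASTOID_POLAR_DEG, -_MASTOID_AZIMUTH_DEG, radius)
    pos["M2"] = _sph(_MASTOID_POLAR_DEG, _MASTOID_AZIMUTH_DEG, radius)
    order = [
        "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4",
        "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2", "M1", "M2",
    ]
    return [(lab, pos[lab]) for lab in order]


def _ten10_rows(radius: float) -> list[tuple[str, np.ndarray]]:
    """71-channel 10/10 layout built from the nomenclature's coronal chains.

    Each chain runs from the left 72-degree-ring electrode through the
    midline to the right one; inner electrodes divide the half-arc in
    quarters (or halves for the short AF/PO chains).  A lower ring at 90
    degrees polar angle adds the '9/10' chain, whose TP9/TP10 members sit at
    mastoid-like positions and serve as the linked-mastoid channels.
    """
    out: list[tuple[str, np.ndarray]] = []

    def chain(mid_label: str, mid_polar: float, mid_az: float, stem: str,
              edge: str, ring_az: float, fracs: list[tuple[str, str, float]]) -> None:
        midp = _sph(mid_polar, mid_az, radius)
        lring = _sph(72, -ring_az, radius)
        rring = _sph(72, ring_az, radius)
        left = [(f"{stem}{a}" if f < 1 else f"{edge}{a}", _slerp(midp, lring, f))
                for a, _, f in fracs]
        right = [(f"{stem}{b}" if f < 1 else f"{edge}{b}", _slerp(midp, rring, f))
                 for _, b, f in fracs]
        out.extend(reversed(left))
        out.append((mid_label, midp))
        out.extend(right)

    full = [("1", "2", 0.25), ("3", "4", 0.5), ("5", "6", 0.75), ("7", "8", 1.0)]
    short = [("3", "4", 0.5), ("7", "8", 1.0)]

    out += [("Fp1", _sph(72, -18, radius)), ("Fpz", _sph(72, 0, radius)),
            ("Fp2", _sph(72, 18, radius))]
    chain("AFz", 54, 0, "AF", "AF", 36, short)
    chain("Fz", 36, 0, "F", "F", 54, full)
    chain("FCz", 18, 0, "FC", "FT", 72, full)
    chain("Cz", 0, 0, "C", "T", 90, full)
    chain("CPz", 18, 180, "CP", "TP", 108, full)
    chain("Pz", 36, 180, "P", "P", 126, full)
    chain("POz", 54, 180, "PO", "PO", 144, short)
    out += [("O1", _sph(72, -162, radius)), ("Oz", _sph(72, 180, radius)),
            ("O2", _sph(72, 162, radius))]
    lower = [
        ("F9", -54), ("F10", 54), ("FT9", -72), ("FT10", 72),
        ("TP9", -108), ("TP10", 108), ("P9", -126), ("P10", 126),
        ("PO9", -144), ("PO10", 144),
    ]
    # the 9/10 chain sits at the below-ear level of the mastoid ring, so the
    # 71-channel net covers strictly more of the head than the 21-channel one
    out.extend((lab, _sph(_MASTOID_POLAR_DEG, az, radius)) for lab, az in lower)
    return out


def _dense_rows(name: str, n_channels: int, radius: float) -> list[tuple[str, np.ndarray]]:
    cap = CAP_ANGLE_DEG[name]
    pts = _fibonacci_cap(n_channels - 3, cap, radius)
    rows: list[tuple[str, np.ndarray]] = [("Cz", np.array([0.0, 0.0, radius]))]
    rows.extend((f"E{i + 1:03d}", p) for i, p in enumerate(pts))
    rows.append(("M1", _sph(_MASTOID_POLAR_DEG, -_MASTOID_AZIMUTH_DEG, radius)))
    rows.append(("M2", _sph(_MASTOID_POLAR_DEG, _MASTOID_AZIMUTH_DEG, radius)))
    return rows


_MASTOID_LABELS_LEFT = ("m1", "tp9", "a1", "lm")
_MASTOID_LABELS_RIGHT = ("m2", "tp10", "a2", "rm")


def _designate(rows: list[tuple[str, np.ndarray]]) -> tuple[int, int, int]:
    labels = [lab.lower() for lab, _ in rows]
    try:
        cz = labels.index("cz")
    except ValueError:
        raise ConfigurationError("montage has no Cz channel") from None
    left = next((i for i, l in enumerate(labels) if l in _MASTOID_LABELS_LEFT), None)
    right = next((i for i, l in enumerate(labels) if l in _MASTOID_LABELS_RIGHT), None)
    if left is None or right is None:
        raise ConfigurationError("montage has no designated mastoid channels")
    return cz, left, right


def make_standard_montage(
    name: str, scalp_radius_mm: float = DEFAULT_SCALP_RADIUS_MM
) -> Montage:
    """Construct one of the built-in spherical montages.

    Parameters
    ----------
    name
        ``ten20_21`` (10/20 system, 21 channels), ``ten10_71`` (10/10
        system, 71 channels), ``dense_128`` or ``dense_256`` (geodesic-style
        Fibonacci caps).
    scalp_radius_mm
        Radius of the scalp sphere the electrodes sit on.
    """
    if name not in STANDARD_MONTAGES:
        raise ConfigurationError(
            f"unknown montage {name!r}; choose from {sorted(STANDARD_MONTAGES)}"
        )
    if scalp_radius_mm <= 0:
        raise ConfigurationError("scalp radius must be positive")
    if name == "ten20_21":
        rows = _ten20_rows(scalp_radius_mm)
    elif name == "ten10_71":
        rows = _ten10_rows(scalp_radius_mm)
    else:
        rows = _dense_rows(name, STANDARD_MONTAGES[name], scalp_radius_mm)
    assert len(rows) == STANDARD_MONTAGES[name], (name, len(rows))
    cz, lm, rm = _designate(rows)
    fiducials = {
        "nasion": _sph(90, 0, scalp_radius_mm),
        "lpa": _sph(90, -90, scalp_radius_mm),
        "rpa": _sph(90, 90, scalp_radius_mm),
    }
    m = Montage(
        electrodes=tuple(Electrode(lab, pos) for lab, pos in rows),
        scalp_radius_mm=scalp_radius_mm,
        cz_index=cz,
        left_mastoid_index=lm,
        right_mastoid_index=rm,
        fiducials=fiducials,
        name=name,
    )
    m.assert_on_sphere()
    return m


# ---------------------------------------------------------------------------
# file I/O (SFP-style: "label x y z" per line, mm, '#' comments)


def write_montage(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        fh.write("# neuroref montage (label x y z, mm)\n")
        if montage.fiducials:
            for key in _FIDUCIAL_LABELS:
                if key in montage.fiducials:
                    x, y, z = montage.fiducials[key]
                    fh.write(f"{key} {x:.8f} {y:.8f} {z:.8f}\n")
        for e in montage.electrodes:
            x, y, z = e.position
            fh.write(f"{e.label} {x:.8f} {y:.8f} {z:.8f}\n")


def read_montage(path) -> Montage:
    rows: list[tuple[str, np.ndarray]] = []
    fiducials: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: expected 'label x y z', got {len(parts)} fields"
                )
            label = parts[0]
            try:
                xyz = np.array([float(v) for v in parts[1:]])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric coordinate"
                ) from None
            if label.lower() in _FIDUCIAL_LABELS:
                fiducials[label.lower()] = xyz
            else:
                if label in [lab for lab, _ in rows]:
                    raise ValidationError(f"{path}: duplicate electrode label {label!r}")
                rows.append((label, xyz))
    if len(rows) < 3:
        raise ValidationError(f"{path}: montage needs at least 3 electrodes, found {len(rows)}")
    cz, lm, rm = _designate(rows)
    radius = float(np.mean([np.linalg.norm(p) for _, p in rows]))
    return Montage(
        electrodes=tuple(Electrode(lab, pos) for lab, pos in rows),
        scalp_radius_mm=radius,
        cz_index=cz,
        left_mastoid_index=lm,
        right_mastoid_index=rm,
        fiducials=fiducials or None,
    )


# ---------------------------------------------------------------------------
# perturbation and alignment


def perturb_positions(
    montage: Montage, mode: str, magnitude_mm: float, seed: int
) -> Montage:
    """Displace electrode positions, emulating digitisation errors.

    ``random``: each electrode is displaced independently by an isotropic
    Gaussian vector whose expected norm equals ``magnitude_mm``.
    ``systematic``: all electrodes are displaced by one shared random vector
    of norm ``magnitude_mm`` (a common misplacement of the whole net).
    In both modes the displaced electrodes are re-projected onto the scalp
    sphere, where real electrodes physically sit.
    """
    if mode not in ("random", "systematic"):
        raise ConfigurationError(f"unknown perturbation mode {mode!r}")
    if magnitude_mm < 0:
        raise ValidationError("perturbation magnitude must be non-negative")
    if magnitude_mm == 0:
        return montage
    rng = np.random.default_rng(seed)
    pos = montage.positions
    if mode == "random":
        # per-component SD such that E||delta|| = magnitude for a 3-D Gaussian
        sigma = magnitude_mm * math.sqrt(math.pi / 8.0)
        delta = rng.standard_normal(pos.shape) * sigma
    else:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        delta = magnitude_mm * direction[None, :]
    new = _project_to_sphere(pos + delta, montage.scalp_radius_mm)
    return montage.with_positions(new)


def rigid_align(montage: Montage, headshape: HeadShape) -> Montage:
    """Least-squares rigid (rotation + translation) alignment of a montage.

    The headshape points are taken as the reference positions of the
    electrodes, in the same order (one point per channel).  The closed-form
    Kabsch/Procrustes solution is used; no scaling is applied.
    """
    pos = montage.positions
    ref = headshape.points
    if ref.shape != pos.shape:
        raise ValidationError(
            f"headshape has {ref.shape[0]} points but montage has {pos.shape[0]} electrodes"
        )
    p_mean = pos.mean(axis=0)
    r_mean = ref.mean(axis=0)
    p_c = pos - p_mean
    r_c = ref - r_mean
    h = p_c.T @ r_c
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise NumericalError("degenerate (collinear) point sets: rigid fit is ill-posed")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    aligned = (rot @ p_c.T).T + r_mean
    return montage.with_positions(aligned)
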