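"""Fidelity metrics for re-referencing operators.

Global relative error (gRE) compares a re-referenced map with the
reference-free (infinity-referenced) truth map over all channels:

    gRE = || V_reref - V || / || V ||        (Euclidean / Frobenius norms)

The channel-based relative error (cRE) is the signed per-channel version,
(V_reref(i) - V(i)) / V(i); negative values mean the method attenuates the
signal at that channel.  Channels where the truth potential is close to
zero are excluded (the ratio is meaningless there).

The artifact reduction index (ARI) of an operator R for an artifact with
spatial pattern a is the ratio of average artifact power across channels
after and before re-referencing:

    ARI = mean((R a)^2) / mean(a^2)

0 means complete elimination, 1 unchanged, > 1 amplification.  Because the
operators are purely spatial and linear, the artifact's time course factors
out and the index depends on the spatial pattern only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, UndefinedMetricError, ValidationError
from .montage import Montage
from .reref import ScalpMap, TransferMatrix

__all__ = [
    "RegionMap",
    "RegionSummary",
    "ArtifactPattern",
    "make_regions",
    "gre",
    "cre",
    "region_cre",
    "ari",
    "make_artifact",
]

#: channels with |V(i)| below this fraction of max|V| are excluded from cRE
SMALL_DENOMINATOR_FRACTION = 1e-3

DEFAULT_PATCH_WIDTH_DEG = 25.0


@dataclass(frozen=True)
class RegionMap:
    """Named, disjoint channel groups (indices into a montage)."""

    regions: dict[str, tuple[int, ...]]
    n_channels: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        regions = {}
        for name, idx in self.regions.items():
            idx = tuple(int(i) for i in idx)
            for i in idx:
                if not (0 <= i < self.n_channels):
                    raise ValidationError(f"region {name!r}: channel index {i} invalid")
                if i in seen:
                    raise ValidationError(f"region {name!r}: channel {i} in two regions")
                seen.add(i)
            regions[name] = idx
        object.__setattr__(self, "regions", regions)


@dataclass(frozen=True)
class RegionSummary:
    """Mean signed cRE over the unguarded channels of one region."""

    mean: float | None
    n_used: int
    n_excluded: int


@dataclass(frozen=True)
class ArtifactPattern:
    """A spatial artifact topography over the channels of a montage."""

    spatial: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vec = np.asarray(self.spatial, dtype=float).ravel()
        if not np.all(np.isfinite(vec)):
            raise ValidationError("artifact pattern must be finite")
        if self.kind == "homogeneous" and vec.size and np.ptp(vec) != 0:
            raise ValidationError("homogeneous artifact must be constant across channels")
        object.__setattr__(self, "spatial", vec)


def make_regions(
    montage: Montage,
    frontal_y_fraction: float = 0.25,
    occipital_y_fraction: float = -0.25,
    occipital_z_fraction: float = 0.5,
) -> RegionMap:
    """Assign channels to frontal / central-parietal / occipital groups.

    Assignment is purely geometric: frontal channels lie anterior of
    ``frontal_y_fraction * R``; occipital channels are posterior and low;
    the central-parietal group is the remaining superior (z > 0) scalp.
    Inferior-lateral channels (e.g. mastoids) belong to no group.
    """
    pos = montage.positions
    r = montage.scalp_radius_mm
    y, z = pos[:, 1], pos[:, 2]
    frontal = y > frontal_y_fraction * r
    occipital = (y < occipital_y_fraction * r) & (z < occipital_z_fraction * r)
    central_parietal = (z > 0) & ~frontal & ~occipital
    return RegionMap(
        regions={
            "frontal": tuple(np.flatnonzero(frontal)),
            "central_parietal": tuple(np.flatnonzero(central_parietal)),
            "occipital": tuple(np.flatnonzero(occipital)),
        },
        n_channels=montage.n_channels,
    )


def _as_values(m) -> np.ndarray:
    if isinstance(m, ScalpMap):
        return m.values
    v = np.asarray(m, dtype=float)
    return v[:, None] if v.ndim == 1 else v


def gre(reref_map, truth_map) -> float:
    """Global relative error between a re-referenced and the truth map."""
    v_re = _as_values(reref_map)
    v = _as_values(truth_map)
    if v_re.shape != v.shape:
        raise ValidationError(f"shape mismatch: {v_re.shape} vs {v.shape}")
    denom = np.linalg.norm(v)
    if denom == 0:
        raise UndefinedMetricError("gRE undefined for an all-zero truth map")
    return float(np.linalg.norm(v_re - v) / denom)


def cre(reref_map, truth_map, channel: int) -> float | None:
    """Signed channel-based relative error; None if the channel is guarded."""
    v_re = _as_values(reref_map)
    v = _as_values(truth_map)
    if v_re.shape != v.shape:
        raise ValidationError(f"shape mismatch: {v_re.shape} vs {v.shape}")
    if v.shape[1] != 1:
        raise ValidationError("cRE is defined on single-sample maps")
    vmax = np.abs(v).max()
    if vmax == 0:
        raise UndefinedMetricError("cRE undefined for an all-zero truth map")
    vi = v[channel, 0]
    if abs(vi) < SMALL_DENOMINATOR_FRACTION * vmax:
        return None
    return float((v_re[channel, 0] - vi) / vi)


def region_cre(reref_map, truth_map, regions: RegionMap) -> dict[str, RegionSummary]:
    """Mean signed cRE per region, with the count of excluded channels."""
    out: dict[str, RegionSummary] = {}
    for name, idx in regions.regions.items():
        vals = [cre(reref_map, truth_map, i) for i in idx]
        used = [v for v in vals if v is not None]
        out[name] = RegionSummary(
            mean=float(np.mean(used)) if used else None,
            n_used=len(used),
            n_excluded=len(vals) - len(used),
        )
    return out


def ari(transfer: TransferMatrix, pattern: ArtifactPattern) -> float:
    """Artifact reduction index: channel-mean power ratio after/before."""
    a = pattern.spatial
    if a.size != transfer.n_channels:
        raise ValidationError(
            f"pattern has {a.size} channels, operator expects {transfer.n_channels}"
        )
    power_before = float(np.mean(a**2))
    if power_before == 0:
        raise UndefinedMetricError("ARI undefined for an all-zero artifact pattern")
    out = transfer.matrix @ a
    return float(np.mean(out**2) / power_before)


def _patch_centre_index(montage: Montage) -> int:
    """Most-anterior midline electrode (the frontal pole of the layout)."""
    pos = montage.positions
    midline = np.abs(pos[:, 0]) <= 0.15 * montage.scalp_radius_mm
    candidates = np.flatnonzero(midline) if midline.any() else np.arange(len(pos))
    return int(candidates[np.argmax(pos[candidates, 1])])


def make_artifact(
    kind: str,
    montage: Montage,
    params: dict | None = None,
    seed: int | None = None,
) -> ArtifactPattern:
    """Build one of the three canonical artifact topographies.

    ``patch``: a non-negative bump centred on the frontal-pole electrode and
    decaying as a Gaussian of the angular distance (ocular-artifact-like);
    ``homogeneous``: the same value on every channel (power-line-like);
    ``random``: i.i.d. standard Gaussian values (sensor-noise-like, seeded).
    """
    params = dict(params or {})
    n = montage.n_channels
    amplitude = float(params.pop("amplitude", 1.0))
    if kind == "homogeneous":
        spatial = np.full(n, amplitude)
    elif kind == "random":
        rng = np.random.default_rng(seed)
        spatial = amplitude * rng.standard_normal(n)
        params["seed"] = seed
    elif kind == "patch":
        width_deg = float(params.pop("width_deg", DEFAULT_PATCH_WIDTH_DEG))
        centre = params.pop("centre_label", None)
        ci = montage.index_of(centre) if centre else _patch_centre_index(montage)
        pos = montage.positions
        units = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        cosang = np.clip(units @ units[ci], -1.0, 1.0)
        ang_deg = np.degrees(np.arccos(cosang))
        spatial = amplitude * np.exp(-((ang_deg / width_deg) ** 2))
        params.update(centre_label=montage.labels[ci], width_deg=width_deg)
    else:
        raise ConfigurationError(f"unknown artifact kind {kind!r}")
    params["amplitude"] = amplitude
    return ArtifactPattern(spatial=spatial, kind=kind, params=params)
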