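"""Re-referencing transfer matrices: CzR, LMR, AR and REST.

Re-referencing an N-channel recording V is the linear map V_reref = R V,
where R = I - K subtracts an estimate of the reference signal from every
channel.  The four operators implemented here are

* CzR -- the vertex channel as reference (K has ones in the Cz column);
* LMR -- linked mastoids (K has 0.5 in the two mastoid columns);
* AR  -- average reference (K = ones/N, a projection onto zero-mean maps);
* REST -- reference electrode standardization: the recording is explained
  by equivalent sources on a brain grid via a minimum-norm inverse of the
  channel-demeaned leadfield G_AR = R_AR G, and the source estimate is
  re-projected through G, yielding a map referenced "at infinity":
  R_REST = G pinv(G_AR) R_AR.

Every operator annihilates the constant vector (rows sum to zero), which is
asserted at construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, NumericalError, ValidationError
from .forward import Leadfield
from .montage import Montage

__all__ = [
    "TransferMatrix",
    "ScalpMap",
    "make_czr",
    "make_lmr",
    "make_ar",
    "make_rest",
    "apply",
]

DEFAULT_PINV_TOL = 1e-8


@dataclass(frozen=True)
class ScalpMap:
    """Channel x time potentials with a reference descriptor."""

    values: np.ndarray
    reference: str = "infinity"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.ndim != 2 or vals.shape[1] < 1:
            raise ValidationError("scalp map must be (N,) or (N, T)")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("scalp map contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class TransferMatrix:
    """An N x N re-referencing operator with a method tag."""

    matrix: np.ndarray
    method: str
    provenance: str = ""

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValidationError("transfer matrix must be square")
        row_sums = np.abs(mat.sum(axis=1)).max()
        if row_sums > 1e-10:
            raise NumericalError(
                f"transfer matrix rows must sum to 0 (constant annihilation); "
                f"worst row sum {row_sums:.3g}"
            )
        object.__setattr__(self, "matrix", mat)

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def make_czr(montage: Montage) -> TransferMatrix:
    """Vertex (Cz) reference: subtract the Cz channel from every channel."""
    n = montage.n_channels
    cz = montage.cz_index
    mat = np.eye(n)
    mat[:, cz] -= 1.0
    return TransferMatrix(mat, "CzR", provenance=montage.name)


def make_lmr(montage: Montage) -> TransferMatrix:
    """Linked-mastoid reference: subtract the mean of the two mastoids."""
    n = montage.n_channels
    lm, rm = montage.left_mastoid_index, montage.right_mastoid_index
    mat = np.eye(n)
    mat[:, lm] -= 0.5
    mat[:, rm] -= 0.5
    return TransferMatrix(mat, "LMR", provenance=montage.name)


def make_ar(n_channels: int) -> TransferMatrix:
    """Average reference: subtract the instantaneous mean over all channels."""
    if n_channels < 2:
        raise ValidationError("average reference needs at least 2 channels")
    mat = np.eye(n_channels) - np.full((n_channels, n_channels), 1.0 / n_channels)
    return TransferMatrix(mat, "AR")


def make_rest(leadfield: Leadfield, pinv_tol: float = DEFAULT_PINV_TOL) -> TransferMatrix:
    """Reference electrode standardization from a leadfield matrix.

    Singular values of the demeaned leadfield below ``pinv_tol`` times the
    largest are treated as zero in the Moore-Penrose inverse.
    """
    g = leadfield.gain
    n = g.shape[0]
    if n < 2:
        raise ValidationError("REST needs at least 2 channels")
    r_ar = make_ar(n).matrix
    g_ar = r_ar @ g
    smax = np.linalg.svd(g_ar, compute_uv=False)[0] if g_ar.size else 0.0
    if smax == 0.0:
        raise NumericalError("demeaned leadfield has rank 0; cannot build REST")
    mat = g @ np.linalg.pinv(g_ar, rcond=pinv_tol) @ r_ar
    return TransferMatrix(
        mat,
        "REST",
        provenance=f"{leadfield.model_ref}; {leadfield.montage_ref}; "
        f"{leadfield.grid_ref}; pinv_tol={pinv_tol:g}",
    )


def apply(transfer: TransferMatrix, scalp_map: ScalpMap) -> ScalpMap:
    """Apply the operator sample-by-sample and update the reference tag."""
    if scalp_map.n_channels != transfer.n_channels:
        raise ValidationError(
            f"map has {scalp_map.n_channels} channels, operator expects "
            f"{transfer.n_channels}"
        )
    return ScalpMap(transfer.matrix @ scalp_map.values, reference=transfer.method)
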