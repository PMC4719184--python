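"""Synthetic oddball ERP generation and P300-level measurements.

The generator emulates averaged ERPs from a visual oddball task: rare
(target, 20%) trials carry a parietal P300-like component -- a radially
oriented dipolar source in posterior parietal cortex, forward-projected
through a head model, with a Gaussian time course whose peak latency is
drawn per subject from a uniform range -- while frequent (80%) trials
contain residual noise only.  Averages are emitted in a physical reference
(the vertex channel by default, as in high-density geodesic systems).

The measurement side mirrors standard ERP practice: P300 amplitude/latency
as the maximum in a post-stimulus window, noise as the pre-stimulus RMS,
and across-subject paired comparison of region-of-interest means with the
Wilcoxon signed-rank test plus the Spearman correlation of paired values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, ValidationError
from .forward import HeadModel, SourceGrid, build_leadfield
from .montage import Montage
from .reref import TransferMatrix

__all__ = [
    "EpochSet",
    "ErpMeasures",
    "RoiComparison",
    "generate_oddball",
    "p300_amplitude",
    "prestim_noise",
    "roi_compare",
    "parietal_roi",
    "rereference",
]

DEFAULT_P300_PARAMS = {
    "amplitude_uv": 10.0,          # peak amplitude at the peak channel
    "latency_range_ms": (325.0, 470.0),
    "width_ms": 60.0,              # Gaussian SD of the temporal profile
    "noise_uv": 1.0,               # per-channel residual noise SD of the average
    "sampling_rate": 250.0,
    "epoch_span_ms": (-200.0, 800.0),
    "source_rel": (0.0, -0.45, 0.55),  # parietal source, relative to brain radius
    "reference": "Cz",
}


@dataclass(frozen=True)
class EpochSet:
    """Per-subject, per-condition averaged epochs (microvolts)."""

    data: np.ndarray               # (n_averages, n_channels, n_times)
    times_ms: np.ndarray
    sampling_rate: float
    subjects: tuple[int, ...]
    conditions: tuple[str, ...]    # per average: "frequent" | "rare"
    montage: Montage
    reference: str = "Cz"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times_ms, dtype=float)
        if data.ndim != 3 or data.shape[2] != times.size:
            raise ValidationError("data must be (averages, channels, times)")
        if data.shape[1] != self.montage.n_channels:
            raise ValidationError("channel count does not match montage")
        if not np.all(np.isfinite(data)):
            raise ValidationError("epoch data contains non-finite values")
        if times[0] > -200.0 or times[-1] < 500.0:
            raise ValidationError(
                "epochs must span at least -200 ms pre- and 500 ms post-stimulus"
            )
        if len(self.subjects) != data.shape[0] or len(self.conditions) != data.shape[0]:
            raise ValidationError("subject/condition labels must match averages")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times_ms", times)
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def select(self, condition: str) -> "EpochSet":
        mask = [i for i, c in enumerate(self.conditions) if c == condition]
        if not mask:
            raise ValidationError(f"no averages with condition {condition!r}")
        return replace(
            self,
            data=self.data[mask],
            subjects=tuple(self.subjects[i] for i in mask),
            conditions=tuple(self.conditions[i] for i in mask),
        )


@dataclass(frozen=True)
class ErpMeasures:
    """Per-average, per-channel ERP measurements."""

    subjects: tuple[int, ...]
    p300_amplitude_uv: np.ndarray | None = None   # (n_averages, n_channels)
    p300_latency_ms: np.ndarray | None = None
    prestim_noise_rms_uv: np.ndarray | None = None
    window_ms: tuple[float, float] = (0.0, 0.0)

    @property
    def values(self) -> np.ndarray:
        v = self.p300_amplitude_uv if self.p300_amplitude_uv is not None \
            else self.prestim_noise_rms_uv
        if v is None:
            raise ValidationError("measure set holds no values")
        return v


@dataclass(frozen=True)
class RoiComparison:
    """Paired across-subject comparison of ROI-mean measures."""

    roi_means_a: np.ndarray
    roi_means_b: np.ndarray
    wilcoxon_w: float
    z: float
    p_value: float
    spearman_r: float
    spearman_p: float
    n_subjects: int
    degenerate: bool = False       # all paired differences were zero
    small_sample: bool = False     # < 5 subjects: asymptotic Z unreliable


def write_epochs(epochs: EpochSet, out_dir) -> None:
    """One TSV matrix (channels x times) per average plus a JSON manifest."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, (subj, cond) in enumerate(zip(epochs.subjects, epochs.conditions)):
        name = f"sub{subj:03d}_{cond}.tsv"
        np.savetxt(out_dir / name, epochs.data[i], fmt="%.10e", delimiter="\t")
        files.append({"file": name, "subject": subj, "condition": cond})
    manifest = {
        "sampling_rate_hz": epochs.sampling_rate,
        "t0_index": int(np.argmin(np.abs(epochs.times_ms))),
        "times_ms": epochs.times_ms.tolist(),
        "reference": epochs.reference,
        "channel_labels": epochs.montage.labels,
        "averages": files,
        "units": "microvolt",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def generate_oddball(
    montage: Montage,
    model: HeadModel,
    n_subjects: int,
    seed: int,
    p300_params: dict | None = None,
) -> EpochSet:
    """Simulate rare/frequent averaged epochs with a parietal P300 source."""
    if n_subjects < 1:
        raise ValidationError("need n_subjects >= 1")
    params = dict(DEFAULT_P300_PARAMS)
    params.update(p300_params or {})
    t0, t1 = params["epoch_span_ms"]
    lat0, lat1 = params["latency_range_ms"]
    if not (t0 <= -200.0 and t1 >= 500.0):
        raise ValidationError("epoch span must cover at least [-200, 500] ms")
    if lat0 < t0 or lat1 > t1 or lat0 > lat1:
        raise ValidationError("P300 latency window lies outside the epoch span")
    dt = 1000.0 / params["sampling_rate"]
    times = np.arange(t0, t1 + 0.5 * dt, dt)
    n_ch = montage.n_channels

    # forward-project the parietal source (infinity-referenced topography)
    src = np.asarray(params["source_rel"], dtype=float) * model.brain_radius_mm
    lf = build_leadfield(model, montage, SourceGrid(positions=src[None, :], spacing_mm=0.0))
    radial = src / np.linalg.norm(src)
    topo_inf = lf.gain @ radial  # radial unit moment
    reference = params["reference"]
    if reference == "Cz":
        topo_phys = topo_inf - topo_inf[montage.cz_index]
    elif reference == "infinity":
        topo_phys = topo_inf
    else:
        raise ConfigurationError(f"unknown physical reference {reference!r}")
    peak = np.abs(topo_phys).max()
    if peak == 0:
        raise ValidationError("P300 topography vanished in the chosen reference")
    topo_inf = topo_inf * (params["amplitude_uv"] / peak)

    rng = np.random.default_rng(seed)
    latencies = rng.uniform(lat0, lat1, size=n_subjects)
    # snap to the sample grid (within the latency range) so the sampled
    # peak equals the nominal one
    grid_lat = times[(times >= lat0) & (times <= lat1)]
    if grid_lat.size == 0:
        raise ValidationError("no sample times inside the latency range")
    latencies = grid_lat[np.abs(grid_lat[None, :] - latencies[:, None]).argmin(axis=1)]
    data = np.empty((2 * n_subjects, n_ch, times.size))
    subjects: list[int] = []
    conditions: list[str] = []
    for s in range(n_subjects):
        pulse = np.exp(-0.5 * ((times - latencies[s]) / params["width_ms"]) ** 2)
        pulse[times <= 0] = 0.0  # stimulus-locked component
        signal = topo_inf[:, None] * pulse[None, :]
        for cond in ("rare", "frequent"):
            noise = params["noise_uv"] * rng.standard_normal((n_ch, times.size))
            inf_ref = (signal if cond == "rare" else 0.0) + noise
            if reference == "Cz":
                inf_ref = inf_ref - inf_ref[montage.cz_index][None, :]
            data[len(subjects)] = inf_ref
            subjects.append(s)
            conditions.append(cond)
    return EpochSet(
        data=data,
        times_ms=times,
        sampling_rate=params["sampling_rate"],
        subjects=tuple(subjects),
        conditions=tuple(conditions),
        montage=montage,
        reference=reference,
    )


def rereference(epochs: EpochSet, transfer: TransferMatrix) -> EpochSet:
    """Apply a re-referencing operator to every average."""
    if transfer.n_channels != epochs.data.shape[1]:
        raise ValidationError("operator/channel count mismatch")
    data = np.einsum("ij,ajt->ait", transfer.matrix, epochs.data)
    return replace(epochs, data=data, reference=transfer.method)


def _window_slice(epochs: EpochSet, window: tuple[float, float]) -> np.ndarray:
    w0, w1 = window
    if w0 >= w1:
        raise ValidationError("empty measurement window")
    t = epochs.times_ms
    if w0 < t[0] or w1 > t[-1]:
        raise ValidationError(f"window {window} outside epoch span [{t[0]}, {t[-1]}] ms")
    idx = np.flatnonzero((t >= w0) & (t <= w1))
    if idx.size == 0:
        raise ValidationError("measurement window contains no samples")
    return idx


def p300_amplitude(epochs: EpochSet, window: tuple[float, float] = (200.0, 500.0)) -> ErpMeasures:
    """Maximum amplitude and its latency in the post-stimulus window."""
    idx = _window_slice(epochs, window)
    seg = epochs.data[:, :, idx]
    amp = seg.max(axis=2)
    lat = epochs.times_ms[idx][seg.argmax(axis=2)]
    return ErpMeasures(
        subjects=epochs.subjects,
        p300_amplitude_uv=amp,
        p300_latency_ms=lat,
        window_ms=window,
    )


def prestim_noise(epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)) -> ErpMeasures:
    """Root-mean-square of the pre-stimulus interval, per channel."""
    idx = _window_slice(epochs, window)
    rms = np.sqrt(np.mean(epochs.data[:, :, idx] ** 2, axis=2))
    return ErpMeasures(
        subjects=epochs.subjects, prestim_noise_rms_uv=rms, window_ms=window
    )


def parietal_roi(
    montage: Montage, y_max_fraction: float = 0.0, z_min_fraction: float = 0.4
) -> tuple[int, ...]:
    """Posterior-superior channel group where the P300 (P3b) is maximal."""
    pos = montage.positions
    r = montage.scalp_radius_mm
    mask = (pos[:, 1] < y_max_fraction * r) & (pos[:, 2] > z_min_fraction * r)
    idx = tuple(np.flatnonzero(mask))
    if not idx:
        raise ValidationError("parietal ROI is empty for this montage")
    return idx


def roi_compare(
    measures_a: ErpMeasures,
    measures_b: ErpMeasures,
    roi: tuple[int, ...],
) -> RoiComparison:
    """Paired Wilcoxon signed-rank comparison of per-subject ROI means."""
    if measures_a.subjects != measures_b.subjects:
        raise ValidationError("measure sets cover different subjects")
    a = measures_a.values[:, list(roi)].mean(axis=1)
    b = measures_b.values[:, list(roi)].mean(axis=1)
    n = a.size
    diffs = b - a
    rho, rho_p = stats.spearmanr(a, b) if n > 2 else (np.nan, np.nan)
    nz = diffs[diffs != 0.0]  # zero differences are dropped (Wilcoxon's rule)
    if nz.size == 0:
        return RoiComparison(
            roi_means_a=a, roi_means_b=b, wilcoxon_w=np.nan, z=0.0, p_value=1.0,
            spearman_r=float(rho), spearman_p=float(rho_p), n_subjects=n,
            degenerate=True, small_sample=n < 5,
        )
    # signed-rank statistic and its plain normal approximation; the sign of
    # z is positive when B exceeds A.  Ties in |d| share midranks but no
    # tie correction is applied to the variance (conservative).
    m = nz.size
    ranks = stats.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    mu = m * (m + 1) / 4.0
    sd = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    z = (w_plus - mu) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RoiComparison(
        roi_means_a=a, roi_means_b=b, wilcoxon_w=w_plus, z=float(z), p_value=p,
        spearman_r=float(rho), spearman_p=float(rho_p), n_subjects=n,
        small_sample=n < 5,
    )
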