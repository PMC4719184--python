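"""Synthetic oddball ERP generation and P300 measurement pipeline."""

import numpy as np
import pytest

from neuroref.erp import (
    ErpMeasures,
    generate_oddball,
    p300_amplitude,
    parietal_roi,
    prestim_noise,
    rereference,
    roi_compare,
    write_epochs,
)
from neuroref.exceptions import ValidationError
from neuroref.forward import HeadModel, build_leadfield, make_source_grid
from neuroref.reref import make_ar, make_rest


@pytest.fixture(scope="module")
def epochs128(mon128, sphere3):
    return generate_oddball(mon128, sphere3, n_subjects=10, seed=42)


def test_determinism(mon21, sphere3):
    a = generate_oddball(mon21, sphere3, 3, seed=9)
    b = generate_oddball(mon21, sphere3, 3, seed=9)
    np.testing.assert_array_equal(a.data, b.data)


def test_noise_free_amplitude_and_silence(mon128, sphere3):
    """Without noise the rare average peaks exactly at the configured
    amplitude and the pre-stimulus interval is exactly silent."""
    ep = generate_oddball(mon128, sphere3, 4, seed=1, p300_params={"noise_uv": 0.0})
    rare = ep.select("rare")
    amp = p300_amplitude(rare)
    np.testing.assert_allclose(amp.p300_amplitude_uv.max(axis=1), 10.0, rtol=1e-9)
    assert prestim_noise(rare).prestim_noise_rms_uv.max() == 0.0
    freq = ep.select("frequent")
    assert np.abs(freq.data).max() == 0.0


def test_latency_bounds_respected(mon21, sphere3):
    ep = generate_oddball(
        mon21, sphere3, 200, seed=3, p300_params={"noise_uv": 0.0}
    )
    rare = ep.select("rare")
    amp = p300_amplitude(rare)
    peak_ch = amp.p300_amplitude_uv.argmax(axis=1)
    lats = amp.p300_latency_ms[np.arange(len(peak_ch)), peak_ch]
    assert lats.min() >= 325.0 and lats.max() <= 470.0
    assert lats.max() - lats.min() > 50.0  # latencies actually vary


def test_single_pulse_measured_exactly(mon21):
    """A half-sine of amplitude A peaking at 350 ms is measured as amplitude
    A at latency 350 ms."""
    from neuroref.erp import EpochSet

    times = np.arange(-200.0, 801.0, 2.0)
    data = np.zeros((1, 21, times.size))
    half = np.sin(np.pi * (times - 300.0) / 100.0)
    half[(times < 300.0) | (times > 400.0)] = 0.0
    data[0, 5] = 3.5 * half
    ep = EpochSet(
        data=data, times_ms=times, sampling_rate=500.0, subjects=(0,),
        conditions=("rare",), montage=mon21, reference="infinity",
    )
    m = p300_amplitude(ep)
    assert m.p300_amplitude_uv[0, 5] == pytest.approx(3.5)
    assert m.p300_latency_ms[0, 5] == pytest.approx(350.0)


def test_prestim_rms_matches_noise_sd(mon21, sphere3):
    """White pre-stimulus noise of SD sigma gives RMS ~ sigma over a long
    window (Monte-Carlo over channels and subjects)."""
    ep = generate_oddball(
        mon21, sphere3, 30, seed=8,
        p300_params={"noise_uv": 2.0, "reference": "infinity"},
    )
    rms = prestim_noise(ep.select("rare")).prestim_noise_rms_uv
    assert abs(np.sqrt(np.mean(rms**2)) - 2.0) / 2.0 < 0.05


def test_window_validation(epochs128):
    with pytest.raises(ValidationError):
        p300_amplitude(epochs128, window=(400.0, 400.0))
    with pytest.raises(ValidationError):
        p300_amplitude(epochs128, window=(200.0, 2000.0))


def test_ar_pipeline_zero_channel_mean(epochs128, mon128):
    out = rereference(epochs128.select("rare"), make_ar(mon128.n_channels))
    assert np.abs(out.data.mean(axis=1)).max() < 1e-12


class TestRoiCompare:
    def test_identical_inputs_degenerate(self, epochs128):
        m = p300_amplitude(epochs128.select("rare"))
        roi = parietal_roi(epochs128.montage)
        res = roi_compare(m, m, roi)
        assert res.degenerate and res.z == 0.0 and res.p_value == 1.0

    def test_constant_offset_gives_extreme_z(self, epochs128):
        """All-positive paired differences yield the maximal signed-rank
        statistic, whose normal approximation has the closed form
        z = (n(n+1)/4) / sqrt(n(n+1)(2n+1)/24)."""
        m = p300_amplitude(epochs128.select("rare"))
        shifted = ErpMeasures(
            subjects=m.subjects, p300_amplitude_uv=m.p300_amplitude_uv + 1.0
        )
        roi = parietal_roi(epochs128.montage)
        res = roi_compare(m, shifted, roi)
        n = res.n_subjects
        z_max = (n * (n + 1) / 4.0) / np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        assert res.z == pytest.approx(z_max)
        assert res.wilcoxon_w == n * (n + 1) / 2.0

    def test_rest_preserves_more_parietal_amplitude_than_ar(
        self, epochs128, mon128, sphere3
    ):
        """AR subtracts the (positive) channel mean of the spatially coherent
        parietal P300, so the REST-referenced ROI amplitude exceeds the
        AR-referenced one in most subjects."""
        grid = make_source_grid(sphere3, spacing_mm=20.0)
        rest = make_rest(build_leadfield(sphere3, mon128, grid))
        ar = make_ar(mon128.n_channels)
        rare = epochs128.select("rare")
        m_ar = p300_amplitude(rereference(rare, ar))
        m_rest = p300_amplitude(rereference(rare, rest))
        roi = parietal_roi(mon128)
        res = roi_compare(m_ar, m_rest, roi)
        frac = np.mean(res.roi_means_b > res.roi_means_a)
        assert frac > 0.5
        assert res.z > 0


def test_write_epochs(tmp_path, mon21, sphere3):
    ep = generate_oddball(mon21, sphere3, 2, seed=0)
    write_epochs(ep, tmp_path / "erp")
    import json

    manifest = json.loads((tmp_path / "erp" / "manifest.json").read_text())
    assert len(manifest["averages"]) == 4
    first = np.loadtxt(tmp_path / "erp" / manifest["averages"][0]["file"])
    np.testing.assert_allclose(first, ep.data[0], rtol=1e-9)
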