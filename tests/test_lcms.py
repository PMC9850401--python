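"""EIC extraction, peak detection/integration, S/N estimation, and run I/O."""

from __future__ import annotations

import math

import numpy as np
import pytest

import glycoquant as gq
from glycoquant.lcms import EIC, ChromPeak, Run, SpectrumRecord, estimate_snr
from glycoquant.mzml import MzMLParseError


def gaussian_eic(area=1e6, rt0=5.0, sigma=0.1, dt=0.02, t_max=10.0, noise=0.0, seed=0, baseline=0.0):
    rt = np.arange(0.0, t_max, dt)
    height = area / (sigma * math.sqrt(2 * math.pi))
    y = height * np.exp(-0.5 * ((rt - rt0) / sigma) ** 2) + baseline
    if noise > 0:
        y = y + noise * np.random.default_rng(seed).standard_normal(rt.size)
    return EIC(500.0, 15.0, rt, np.clip(y, 0, None))


class TestRunIO:
    def test_mzml_round_trip(self, tmp_path, toy_polys):
        run, _ = gq.simulate_run({"starchlet": 500.0}, toy_polys,
                                 gq.SimConfig(seed=3, gradient_min=8.0))
        path = tmp_path / "run.mzML"
        gq.lcms.write_mzml(run, path)
        back = gq.read_run(path)
        assert len(back) == len(run)
        for a, b in zip(run, back):
            assert b.ms_level == a.ms_level
            assert b.rt == pytest.approx(a.rt, abs=1e-9)
            np.testing.assert_allclose(b.mz, a.mz)
            np.testing.assert_allclose(b.intensity, a.intensity)

    def test_mzml_round_trip_preserves_eic(self, tmp_path, toy_polys):
        run, truth = gq.simulate_run({"arabinlet": 800.0}, toy_polys,
                                     gq.SimConfig(seed=4, gradient_min=8.0))
        path = tmp_path / "run.mzML"
        gq.lcms.write_mzml(run, path)
        back = gq.read_run(path)
        mz = float(truth.mz.iloc[0])
        a = gq.extract_eic(run, mz)
        b = gq.extract_eic(back, mz)
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)

    def test_mzml_ms2_metadata_round_trip(self, tmp_path, toy_polys):
        cfg = gq.SimConfig(seed=5, gradient_min=8.0, include_ms2=True)
        run, _ = gq.simulate_run({"chitinlet": 1000.0}, toy_polys, cfg)
        ms2 = run.ms2
        assert ms2, "simulation produced no MS2 scans"
        path = tmp_path / "run.mzML"
        gq.lcms.write_mzml(run, path)
        back_ms2 = gq.read_run(path).ms2
        assert len(back_ms2) == len(ms2)
        assert back_ms2[0].precursor_mz == pytest.approx(ms2[0].precursor_mz)
        assert back_ms2[0].precursor_charge == ms2[0].precursor_charge

    def test_empty_run_round_trip(self, tmp_path):
        path = tmp_path / "empty.mzML"
        gq.lcms.write_mzml([], path)
        assert len(gq.read_run(path)) == 0

    def test_truncated_mzml_raises_parse_error(self, tmp_path, toy_polys):
        run, _ = gq.simulate_run({"starchlet": 500.0}, toy_polys,
                                 gq.SimConfig(seed=3, gradient_min=8.0))
        path = tmp_path / "run.mzML"
        gq.lcms.write_mzml(run, path)
        text = path.read_text()
        (tmp_path / "trunc.mzML").write_text(text[: len(text) // 2])
        with pytest.raises(MzMLParseError):
            gq.read_run(tmp_path / "trunc.mzML")

    def test_mgf_blocks(self, tmp_path):
        blocks = "\n".join(
            f"BEGIN IONS\nTITLE=scan={i}\nPEPMASS=529.17 1e5\nRTINSECONDS={60 * i}\n"
            f"CHARGE=1+\n100.1 10.0\n200.2 20.0\nEND IONS\n"
            for i in range(1, 4)
        )
        path = tmp_path / "three.mgf"
        path.write_text(blocks)
        run = gq.read_run(path)
        assert len(run) == 3
        assert all(s.ms_level == 2 for s in run)
        assert run[1].rt == pytest.approx(2.0)  # RTINSECONDS converted to minutes

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "run.raw"
        p.write_text("")
        with pytest.raises(ValueError, match="unsupported run format"):
            gq.read_run(p)


class TestExtractEic:
    def test_reproduces_single_gaussian_pointwise(self, toy_polys):
        run, truth = gq.simulate_run({"starchlet": 400.0}, toy_polys,
                                     gq.SimConfig(seed=9, gradient_min=8.0, noise_rel=0.0))
        row = truth.iloc[0]
        eic = gq.extract_eic(run, float(row.mz))
        ms1 = run.ms1
        expected = np.array([
            s.intensity[np.abs(s.mz - row.mz) <= row.mz * 15e-6].sum() for s in ms1
        ])
        np.testing.assert_allclose(eic.intensity, expected)
        assert eic.rt[eic.intensity.argmax()] == pytest.approx(row.rt, abs=0.05)

    def test_off_target_is_all_zero(self, toy_polys):
        run, truth = gq.simulate_run({"starchlet": 400.0}, toy_polys,
                                     gq.SimConfig(seed=9, gradient_min=8.0, noise_rel=0.0))
        mz = float(truth.mz.iloc[0]) * (1 + 50e-6)
        eic = gq.extract_eic(run, mz, tolerance_ppm=10)
        assert np.all(eic.intensity == 0)

    def test_no_crosstalk_between_series(self, toy_polys):
        """Co-eluting masses separated by >> 2x tolerance stay independent."""
        both, truth = gq.simulate_run({"starchlet": 400.0, "arabinlet": 400.0},
                                      toy_polys, gq.SimConfig(seed=9, gradient_min=8.0, noise_rel=0.0))
        solo, truth_solo = gq.simulate_run({"starchlet": 400.0}, toy_polys,
                                           gq.SimConfig(seed=9, gradient_min=8.0, noise_rel=0.0))
        mz = float(truth_solo.mz.iloc[0])
        np.testing.assert_allclose(
            gq.extract_eic(both, mz).intensity,
            gq.extract_eic(solo, mz).intensity,
            rtol=1e-12,
        )

    def test_requires_ms1(self):
        rec = SpectrumRecord("s1", 2, 1.0, np.array([100.0]), np.array([1.0]), precursor_mz=500.0)
        with pytest.raises(ValueError, match="no MS1"):
            gq.extract_eic(Run([rec]), 500.0)


class TestDetectPeaks:
    def test_single_gaussian_area_within_2pct(self):
        eic = gaussian_eic(area=2.5e6)
        peaks = gq.detect_peaks(eic)
        assert len(peaks) == 1
        assert peaks[0].area == pytest.approx(2.5e6, rel=0.02)
        assert peaks[0].apex_rt == pytest.approx(5.0, abs=0.03)

    def test_flat_noise_yields_nothing(self):
        rng = np.random.default_rng(0)
        eic = EIC(500.0, 15.0, np.arange(0, 10, 0.02),
                  np.abs(100 + 10 * rng.standard_normal(500)))
        assert gq.detect_peaks(eic, min_snr=3) == []

    def test_two_gaussians_resolved(self):
        rt = np.arange(0.0, 10.0, 0.02)
        h = 1e6
        y = h * np.exp(-0.5 * ((rt - 4.0) / 0.2) ** 2) + h * np.exp(-0.5 * ((rt - 6.0) / 0.2) ** 2)
        peaks = gq.detect_peaks(EIC(500.0, 15.0, rt, y))
        assert len(peaks) == 2
        assert peaks[0].apex_rt == pytest.approx(4.0, abs=0.03)
        assert peaks[1].apex_rt == pytest.approx(6.0, abs=0.03)

    def test_scaling_invariance(self):
        eic = gaussian_eic(area=1e6, noise=2e4, seed=11, baseline=1e5)
        scaled = EIC(eic.target_mz, eic.tolerance_ppm, eic.rt, eic.intensity * 37.0)
        p1 = gq.detect_peaks(eic)
        p2 = gq.detect_peaks(scaled)
        assert len(p1) == len(p2) == 1
        assert p2[0].apex_rt == p1[0].apex_rt
        assert p2[0].area == pytest.approx(37.0 * p1[0].area, rel=1e-9)
        assert p2[0].height == pytest.approx(37.0 * p1[0].height, rel=1e-9)

    def test_boundaries_never_overlap(self):
        rng = np.random.default_rng(5)
        rt = np.arange(0.0, 20.0, 0.02)
        y = 5e4 + 1e3 * rng.standard_normal(rt.size)
        for c in np.arange(2.0, 19.0, 1.3):
            y += 3e6 * np.exp(-0.5 * ((rt - c) / 0.15) ** 2)
        peaks = gq.detect_peaks(EIC(500.0, 15.0, rt, np.clip(y, 0, None)))
        assert len(peaks) >= 5
        for a, b in zip(peaks, peaks[1:]):
            assert a.rt_end <= b.rt_start + 1e-12

    def test_too_few_samples_rejected(self):
        eic = EIC(500.0, 15.0, np.array([1.0, 2.0, 3.0]), np.zeros(3))
        with pytest.raises(ValueError, match="min_points"):
            gq.detect_peaks(eic, min_points=5)


class TestEstimateSnr:
    def test_noiseless_peak_snr_capped(self):
        peaks = gq.detect_peaks(gaussian_eic())
        assert peaks[0].snr == gq.lcms.SNR_CAP

    def test_snr_three_for_height_thirty_on_sigma_ten(self):
        """Monte Carlo: height-30 peak on sigma-10 Gaussian noise -> S/N ≈ 3."""
        snrs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rt = np.arange(0.0, 10.0, 0.02)
            y = 100.0 + 10.0 * rng.standard_normal(rt.size)
            y += 30.0 * np.exp(-0.5 * ((rt - 5.0) / 0.1) ** 2)
            eic = EIC(500.0, 15.0, rt, np.clip(y, 0, None))
            apex = int(np.argmin(np.abs(rt - 5.0)))
            peak = ChromPeak(5.0, 4.6, 5.4, area=1.0, height=30.0, snr=np.nan,
                             idx_apex=apex, idx_start=apex - 20, idx_end=apex + 20)
            snrs.append(estimate_snr(eic, peak))
        assert np.mean(snrs) == pytest.approx(3.0, rel=0.15)

    def test_peak_spanning_whole_trace_rejected(self):
        eic = gaussian_eic()
        n = eic.rt.size
        peak = ChromPeak(5.0, 0.1, 9.9, area=1.0, height=1.0, snr=np.nan,
                         idx_apex=n // 2, idx_start=0, idx_end=n - 1)
        with pytest.raises(ValueError, match="no baseline samples"):
            estimate_snr(eic, peak)
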