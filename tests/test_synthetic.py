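"""Synthetic-study generator: determinism, effect faithfulness, recovery."""

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pytest

from cogload import gaze_metrics, pupil_metrics
from cogload.eeg_metrics import band_power, psd
from cogload.flight_metrics import aggressiveness, duty_cycle
from cogload.stats import accuracy_nback
from cogload.synthetic import (
    EffectMap,
    StudyConfig,
    gen_eeg,
    gen_gaze,
    gen_inceptor_flight,
    gen_nback_log,
    gen_pupil,
    gen_study,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        for gen, args in [
            (gen_pupil, (0.5, 10.0, 100.0)),
            (gen_gaze, (0.5, 10.0, 100.0)),
            (gen_eeg, (0.5, 10.0, 128.0)),
        ]:
            a = gen(*args, seed=123)
            b = gen(*args, seed=123)
            if gen is gen_pupil:
                np.testing.assert_array_equal(a[0].diameter, b[0].diameter)
                np.testing.assert_array_equal(a[1].diameter, b[1].diameter)
            elif gen is gen_gaze:
                np.testing.assert_array_equal(
                    a[0].channels["gaze_x_deg"], b[0].channels["gaze_x_deg"]
                )
            else:
                for ch in a.channels:
                    np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_inceptor_flight_deterministic(self):
        (ta, fa, _), (tb, fb, _) = (
            gen_inceptor_flight(0.5, 20.0, seed=9) for _ in range(2)
        )
        np.testing.assert_array_equal(ta.defl, tb.defl)
        np.testing.assert_array_equal(
            fa.channels["altitude_ft"], fb.channels["altitude_ft"]
        )


class TestNullEffectMap:
    def test_zero_gains_remove_every_workload_pathway(self):
        """With all gains zero the workload has no effect on any signal."""
        lo, _ = gen_pupil(0.1, 10.0, seed=1, band_gain=0.0)
        hi, _ = gen_pupil(0.9, 10.0, seed=1, band_gain=0.0)
        np.testing.assert_array_equal(lo.diameter, hi.diameter)

        zero = {b: 0.0 for b in ("theta", "alpha", "low_beta", "high_beta")}
        a = gen_eeg(0.1, 10.0, seed=1, band_gains=zero)
        b = gen_eeg(0.9, 10.0, seed=1, band_gains=zero)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

        (ia, fa, _) = gen_inceptor_flight(0.1, 20.0, seed=1, activity_gain=0.0,
                                          tracking_gain=0.0)
        (ib, fb, _) = gen_inceptor_flight(0.9, 20.0, seed=1, activity_gain=0.0,
                                          tracking_gain=0.0)
        np.testing.assert_array_equal(ia.defl, ib.defl)
        np.testing.assert_array_equal(
            fa.channels["altitude_ft"], fb.channels["altitude_ft"]
        )


class TestPupilGenerator:
    def test_workload_raises_l1ns(self):
        lo, hi = [], []
        for s in range(20):
            (a, _) = gen_pupil(0.0, 10.0, seed=s)[0], None
            ep0, _ = gen_pupil(0.0, 10.0, seed=s)
            ep1, _ = gen_pupil(1.0, 10.0, seed=s)
            lo.append(pupil_metrics.l1ns(ep0))
            hi.append(pupil_metrics.l1ns(ep1))
        from scipy.stats import wilcoxon

        assert np.mean(hi) > np.mean(lo)
        assert wilcoxon(hi, lo, alternative="greater").pvalue < 0.01

    def test_zero_band_and_noise_gives_near_zero_l1ns(self):
        left, _ = gen_pupil(0.0, 10.0, seed=3, base_amplitude=0.0, noise_sd=0.0,
                            blink_rate=0.0, drift_amplitude=0.0)
        assert pupil_metrics.l1ns(left) == pytest.approx(0.0, abs=1e-6)

    def test_eyes_strongly_correlated(self):
        left, right = gen_pupil(0.5, 30.0, seed=4, blink_rate=0.0)
        r = np.corrcoef(left.diameter, right.diameter)[0, 1]
        assert r > 0.85


class TestGazeGenerator:
    def test_dwell_bounds_respected(self):
        _, truth = gen_gaze(0.5, 60.0, seed=5)
        durs = [f["end"] - f["start"] for f in truth["fixations"][:-1]]
        # generated dwells are 200-800 ms (sampling quantisation aside)
        assert all(0.15 <= d <= 0.85 for d in durs)

    def test_dispersion_rises_with_workload(self):
        lo, hi = [], []
        for s in range(12):
            g0, _ = gen_gaze(0.0, 60.0, seed=100 + s)
            g1, _ = gen_gaze(1.0, 60.0, seed=100 + s)
            f0, _ = gaze_metrics.ivt_classify(g0)
            f1, _ = gaze_metrics.ivt_classify(g1)
            lo.append(gaze_metrics.nni(f0).nni)
            hi.append(gaze_metrics.nni(f1).nni)
        from scipy.stats import wilcoxon

        assert wilcoxon(hi, lo, alternative="greater").pvalue < 0.01

    def test_planted_intrusions_recovered(self):
        recovered = planted = 0
        for s in range(6):
            g, truth = gen_gaze(0.5, 120.0, seed=200 + s)
            events = gaze_metrics.detect_si(g)
            for p in truth["si_events"]:
                planted += 1
                if any(abs(e.onset - p["onset"]) < 0.15 for e in events):
                    recovered += 1
        assert planted >= 10
        assert recovered / planted >= 0.9


class TestEEGGenerator:
    def test_band_amplitude_gain_squares_power(self):
        gains0 = {b: 0.0 for b in ("theta", "alpha", "low_beta", "high_beta")}
        a = gen_eeg(1.0, 60.0, seed=6, band_gains=gains0, background_sd=0.0)
        gains1 = dict(gains0, theta=np.sqrt(2) - 1)  # amplitude factor sqrt(2)
        b = gen_eeg(1.0, 60.0, seed=6, band_gains=gains1, background_sd=0.0)
        pa = band_power(psd(a.channels["Pz_uV"], 128.0), "theta")
        pb = band_power(psd(b.channels["Pz_uV"], 128.0), "theta")
        assert pb / pa == pytest.approx(2.0, rel=0.15)

    def test_median_low_beta_monotone_in_workload(self):
        meds = []
        for w in (0.2, 0.5, 0.9):
            vals = []
            for s in range(10):
                rec = gen_eeg(w, 30.0, seed=300 + s)
                vals.append(
                    band_power(psd(rec.channels["Pz_uV"], 128.0), "low_beta")
                )
            meds.append(np.median(vals))
        assert meds[0] < meds[1] < meds[2]


class TestInceptorGenerator:
    @pytest.mark.parametrize("a", [0.2, 0.5, 0.8])
    def test_duty_cycle_recovers_activity_fraction(self, a):
        dcs = []
        for s in range(8):
            # base_activity=a with zero gain pins the active fraction at a
            tr, _, _ = gen_inceptor_flight(
                0.0, 240.0, seed=400 + s, base_activity=a, activity_gain=0.0
            )
            dcs.append(duty_cycle(tr))
        assert np.mean(dcs) == pytest.approx(100.0 * a, abs=5.0)

    def test_idle_only_trace(self):
        tr, _, _ = gen_inceptor_flight(0.0, 60.0, seed=7, base_activity=0.0,
                                       activity_gain=0.0)
        assert duty_cycle(tr) == 0.0
        assert aggressiveness(tr) == pytest.approx(0.0, abs=1e-12)

    def test_tracking_error_rises_with_workload(self):
        from cogload.flight_metrics import FlightReference, rmse_percent

        lo, hi = [], []
        for s in range(20):
            _, f0, _ = gen_inceptor_flight(0.0, 60.0, seed=500 + s)
            _, f1, _ = gen_inceptor_flight(1.0, 60.0, seed=500 + s)
            lo.append(rmse_percent(f0, FlightReference(), "altitude"))
            hi.append(rmse_percent(f1, FlightReference(), "altitude"))
        from scipy.stats import wilcoxon

        assert wilcoxon(hi, lo, alternative="greater").pvalue < 0.01


class TestNbackGenerator:
    def test_perfect_responder(self):
        _, counts = gen_nback_log(1.0, 0.0, 100, level=2, seed=8)
        assert accuracy_nback(counts) == 1.0

    def test_counts_sum_to_trials(self):
        _, counts = gen_nback_log(0.7, 0.1, 250, level=2, seed=9)
        assert counts.total == 250

    def test_accuracy_matches_analytic_expectation(self):
        # accuracy = (p_hit*T + (1-p_fa)*NT) / n; targets occur w.p. 1/9
        p_hit, p_fa, n = 0.8, 0.1, 500
        _, counts = gen_nback_log(p_hit, p_fa, n, level=2, seed=10)
        t_frac = (counts.correct + counts.missed) / n
        expected = p_hit * t_frac + (1 - p_fa) * (1 - t_frac)
        got = accuracy_nback(counts)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(got - expected) < 4 * se


class TestGenStudy:
    def test_study_structure(self, monotone_study):
        cfg, out = monotone_study
        cells = [d for p in Path(out).iterdir() if p.is_dir() for d in p.iterdir()]
        assert len(cells) == 36  # 12 participants x 3 conditions
        for cell in cells:
            names = {f.name for f in cell.iterdir()}
            assert names == {"gaze.csv", "eeg.csv", "inceptor.csv", "flight.csv",
                             "events.csv"}

    def test_manifest_round_trip(self, monotone_study):
        cfg, out = monotone_study
        manifest = json.loads((Path(out) / "manifest.json").read_text())
        assert StudyConfig(**manifest["config"]) == cfg
        assert len(manifest["recordings"]) == 36

    def test_refuses_existing_directory(self, tmp_path):
        out = tmp_path / "study"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            gen_study(StudyConfig(participants=1, duration_s=5.0), out)

    def test_same_seed_identical_files(self, tmp_path):
        cfg = StudyConfig(participants=2, duration_s=6.0, seed=77)
        hashes = []
        for run in ("a", "b"):
            out = tmp_path / run
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gen_study(cfg, out)
            digest = hashlib.sha256()
            for f in sorted(out.rglob("*.csv")):
                digest.update(f.read_bytes())
            hashes.append(digest.hexdigest())
        assert hashes[0] == hashes[1]
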