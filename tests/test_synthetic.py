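import numpy as np
import pytest

from ecgrecon import (
    DipoleParams,
    NoiseConfig,
    add_noise,
    detect_r_peaks,
    fit_linear,
    make_synthetic_record,
    project_leads,
    simulate_dipole,
)
from ecgrecon.exceptions import ConfigError
from ecgrecon.synthetic import WAVE_ORDER, WaveParams

NO_NOISE = NoiseConfig(white_noise_uv=0, baseline_amp_uv=0)


class TestSimulateDipole:
    def test_constant_rate_beat_annotations(self):
        params = DipoleParams(heart_rate_bpm=60, hrv_fraction=0.0)
        traj, ann = simulate_dipole(params, 10, 1000, seed=0)
        assert traj.shape == (3, 10000)
        r = np.array([a.r_sample for a in ann])
        assert r.size == 10
        assert np.all(np.abs(np.diff(r) - 1000) <= 1)

    def test_zero_amplitudes_zero_trajectory(self):
        waves = {w: WaveParams((0.0, 0.0, 0.0),
                               DipoleParams().waves[w].width,
                               DipoleParams().waves[w].center)
                 for w in WAVE_ORDER}
        traj, _ = simulate_dipole(DipoleParams(waves=waves), 5, 1000, seed=0)
        assert np.allclose(traj, 0.0)

    def test_seed_determinism(self):
        p = DipoleParams(hrv_fraction=0.1, pvc_probability=0.2)
        t1, a1 = simulate_dipole(p, 20, 1000, seed=42)
        t2, a2 = simulate_dipole(p, 20, 1000, seed=42)
        assert np.array_equal(t1, t2)
        assert a1 == a2

    def test_too_short_duration_rejected(self):
        with pytest.raises(ConfigError):
            simulate_dipole(DipoleParams(), 1.0, 1000, seed=0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            DipoleParams(pvc_probability=1.5)
        with pytest.raises(ConfigError):
            DipoleParams(heart_rate_bpm=0)


class TestProjectLeads:
    def test_unit_row_extracts_axis(self, rng):
        traj = rng.normal(size=(3, 50))
        rec = project_leads(traj, {"x_only": (1.0, 0.0, 0.0)})
        assert np.array_equal(rec.channel("x_only"), traj[0])

    def test_constant_trajectory_sums_weights(self):
        rec = project_leads(np.ones((3, 10)), {"s": (0.2, 0.3, 0.5)})
        assert np.allclose(rec.channel("s"), 1.0)

    def test_any_channel_linear_in_any_full_rank_triple(self, rng):
        traj = rng.normal(size=(3, 300))
        field = {"a": (1.0, 0.2, 0.0), "b": (0.0, 1.0, 0.3),
                 "c": (0.5, 0.0, 1.0), "target": (0.7, -0.4, 0.9)}
        rec = project_leads(traj, field)
        res = fit_linear(rec.subset(["a", "b", "c"]),
                         rec.subset(["target"]))
        err = res.predict(rec.subset(["a", "b", "c"])) - rec.channel("target")
        assert np.max(np.abs(err)) < 1e-9


class TestAddNoise:
    def test_zero_amplitudes_identity(self, rng):
        from ecgrecon import EcgRecord
        rec = EcgRecord(1000, ["a"], rng.normal(size=(1, 100)))
        out = add_noise(rec, NO_NOISE)
        assert np.array_equal(out.signals, rec.signals)

    def test_white_noise_std_calibrated(self):
        from ecgrecon import EcgRecord
        rec = EcgRecord(1000, ["a", "b"], np.zeros((2, 100_000)))
        out = add_noise(rec, NoiseConfig(white_noise_uv=5.0,
                                         baseline_amp_uv=0, seed=1))
        stds_uv = out.signals.std(axis=1) * 1000
        assert np.all(np.abs(stds_uv - 5.0) / 5.0 < 0.05)

    def test_seed_determinism(self, rng):
        from ecgrecon import EcgRecord
        rec = EcgRecord(1000, ["a"], rng.normal(size=(1, 5000)))
        cfg = NoiseConfig(seed=9)
        assert np.array_equal(add_noise(rec, cfg).signals,
                              add_noise(rec, cfg).signals)


class TestMakeSyntheticRecord:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError, match="preset"):
            make_synthetic_record("weird", 10, 1000)

    def test_einthoven_identities_noiseless(self, clean_record):
        rec, _ = clean_record
        i, ii, iii = (rec.channel(n) for n in ("I", "II", "III"))
        assert np.max(np.abs(i + iii - ii)) <= 1e-9
        avr = rec.channel("aVR") + rec.channel("aVL") + rec.channel("aVF")
        assert np.max(np.abs(avr)) <= 1e-9

    def test_lead_ii_r_peak_calibrated(self, clean_record):
        rec, _ = clean_record
        assert abs(rec.channel("II").max() - 1.0) <= 0.1

    def test_rank3_exact_linear_recovery(self, clean_record):
        """Noiseless channels are exact linear functions of the EASI trio."""
        rec, _ = clean_record
        x = rec.subset(["ES", "AS", "AI"])
        res = fit_linear(x, rec.subset(["V2"]))
        rms_uv = 1000 * np.sqrt(np.mean((res.predict(x)
                                         - rec.channel("V2")) ** 2))
        assert rms_uv < 1e-6

    def test_annotation_fidelity_under_detection(self, clean_record):
        rec, ann = clean_record
        peaks = detect_r_peaks(rec.channel("II"), rec.sampling_rate)
        truth = np.array([a.r_sample for a in ann])
        assert peaks.size == truth.size
        assert np.max(np.abs(peaks - truth)) <= 20

    def test_seed_determinism_end_to_end(self):
        r1, a1 = make_synthetic_record("pvc", 15, 1000, seed=3)
        r2, a2 = make_synthetic_record("pvc", 15, 1000, seed=3)
        assert np.array_equal(r1.signals, r2.signals)
        assert a1 == a2

    def test_pvc_preset_marks_and_shapes_ectopic_beats(self):
        rec, ann = make_synthetic_record("pvc", 120, 1000,
                                         noise=NO_NOISE, seed=8)
        types = {a.beat_type for a in ann}
        assert types == {"normal", "pvc"}
        # a PVC QRS is wider: more samples above half its R amplitude
        ii = rec.channel("II")

        def qrs_width(r):
            lo, hi = max(0, r - 150), min(ii.size, r + 150)
            seg = ii[lo:hi]
            return int(np.sum(seg > 0.5 * seg.max()))

        pvc_w = [qrs_width(a.r_sample) for a in ann if a.beat_type == "pvc"]
        normal_w = [qrs_width(a.r_sample) for a in ann
                    if a.beat_type == "normal"]
        assert np.mean(pvc_w) > 1.5 * np.mean(normal_w)

    def test_nonlinear_preset_breaks_linearity_on_precordials(self):
        rec, _ = make_synthetic_record("nonlinear", 30, 1000,
                                       noise=NO_NOISE, seed=4)
        x = rec.subset(["ES", "AS", "AI"])
        res = fit_linear(x, rec.subset(["V5"]))
        resid = res.predict(x) - rec.channel("V5")
        assert 1000 * np.sqrt(np.mean(resid ** 2)) > 1.0  # > 1 uV
        # but limb leads stay exactly linear
        res2 = fit_linear(x, rec.subset(["II"]))
        resid2 = res2.predict(x) - rec.channel("II")
        assert np.max(np.abs(resid2)) < 1e-9
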