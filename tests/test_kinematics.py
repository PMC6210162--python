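"""Task-signal extraction, cycle segmentation and kinematic feature recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from updrskit.kinematics import (FEATURES, InsufficientCyclesError, TaskSignal,
                                 compute_features, extract_task_signal,
                                 features_for_recording, principal_frequency,
                                 segment_cycles)
from updrskit.synthetic import MotionParams, embed_in_3d, generate_scalar_profile
from updrskit.trajectories import FingertipTrajectory, TaskKind, TaskRecording


def _signal_from(task, A, f, n_cycles, seed=0, **kw):
    p = MotionParams(task=task, base_amplitude=A, base_frequency=f,
                     n_cycles=n_cycles, seed=seed, **kw)
    return extract_task_signal(embed_in_3d(generate_scalar_profile(p)), rate=100)


class TestExtraction:
    def test_coincident_fingertips_give_zero_ft_signal(self):
        t = np.arange(0, 3, 0.02)
        xyz = np.tile([0.0, 0.0, 400.0], (t.size, 1))
        rec = TaskRecording(task="FT", trajectories={
            "thumb": FingertipTrajectory("thumb", t, xyz),
            "index": FingertipTrajectory("index", t, xyz.copy())})
        sig = extract_task_signal(rec)
        assert np.allclose(sig.values, 0.0)

    @pytest.mark.parametrize("task,A,baseline", [("FT", 60.0, 10.0), ("OC", 80.0, 25.0),
                                                 ("PS", 160.0, 0.0)])
    def test_embedding_roundtrip_is_identity_at_native_rate(self, task, A, baseline):
        p = MotionParams(task=task, base_amplitude=A, base_frequency=2.0, n_cycles=6,
                         baseline=baseline, seed=1)
        prof = generate_scalar_profile(p)
        sig = extract_task_signal(embed_in_3d(prof), rate=p.sample_rate)
        n = min(sig.values.size, prof.value.size)
        assert np.max(np.abs(sig.values[:n] - prof.value[:n])) < 1e-6

    def test_ps_uniform_rotation_unwraps_without_discontinuity(self):
        t = np.arange(0, 4, 1 / 60)
        angle = np.linspace(90, -90, t.size)
        p = MotionParams(task="PS", base_amplitude=180, base_frequency=1, n_cycles=4, seed=0)
        prof = generate_scalar_profile(p)
        prof.t, prof.value = t, angle
        sig = extract_task_signal(embed_in_3d(prof, task="PS"), rate=60)
        d = np.diff(sig.values)
        assert np.all(d < 0)                      # monotone ramp
        assert np.max(np.abs(d)) < 2.0            # no wrap jumps

    def test_missing_finger_named_in_error(self, ft_recording):
        rec = TaskRecording(task="FT", trajectories={"thumb": ft_recording["thumb"]})
        with pytest.raises(KeyError, match="index"):
            extract_task_signal(rec)

    def test_large_tracking_gap_rejected(self, ft_recording):
        keep = np.ones(len(ft_recording["index"]), bool)
        n = keep.size
        keep[n // 4: n // 4 + int(0.3 * n)] = False   # 30% contiguous dropout
        trajs = {f: FingertipTrajectory(f, tr.t[keep], tr.xyz[keep])
                 for f, tr in ft_recording.trajectories.items()}
        rec = TaskRecording(task="FT", trajectories=trajs)
        with pytest.raises(ValueError, match="gap"):
            extract_task_signal(rec)

    def test_oc_index_y_mode(self):
        p = MotionParams(task="OC", base_amplitude=80, base_frequency=2, n_cycles=4,
                         baseline=25, seed=0)
        rec = embed_in_3d(generate_scalar_profile(p))
        sig = extract_task_signal(rec, oc_mode="index_y")
        assert sig.values.size > 0
        with pytest.raises(ValueError, match="oc_mode"):
            extract_task_signal(rec, oc_mode="bogus")


class TestSegmentation:
    def test_noise_free_cycles_recovered_exactly(self):
        sig = _signal_from("FT", 60.0, 2.0, 10)
        cyc = segment_cycles(sig)
        assert len(cyc) == 10
        assert np.allclose(cyc["amplitude"], 60.0, atol=0.5)
        assert np.allclose(cyc["duration_s"], 0.5, atol=0.005)

    def test_raised_cosine_peak_speed_is_amplitude_pi_freq(self):
        sig = _signal_from("FT", 60.0, 2.0, 12)
        cyc = segment_cycles(sig)
        expect = 60.0 * np.pi * 2.0
        assert np.mean(cyc["max_speed_opening"]) == pytest.approx(expect, rel=0.01)
        assert np.mean(cyc["max_speed_closing"]) == pytest.approx(expect, rel=0.01)

    def test_flat_signal_reports_insufficient_cycles(self):
        sig = TaskSignal(np.full(500, 30.0), rate=100, task="FT")
        with pytest.raises(InsufficientCyclesError):
            segment_cycles(sig)

    def test_too_short_signal_rejected(self):
        sig = TaskSignal(np.sin(np.arange(100) * 0.1), rate=100, task="FT")
        with pytest.raises(InsufficientCyclesError):
            segment_cycles(sig)


class TestPrincipalFrequency:
    def test_pure_3hz_profile(self):
        sig = _signal_from("FT", 60.0, 3.0, 20)
        assert principal_frequency(sig) == pytest.approx(3.0, abs=0.05)

    def test_jittered_periods_track_mean_cycle_rate(self):
        p = MotionParams(task="FT", base_amplitude=60, base_frequency=2, n_cycles=50,
                         period_cv=0.1, seed=4)
        prof = generate_scalar_profile(p)
        sig = extract_task_signal(embed_in_3d(prof), rate=100)
        f = principal_frequency(sig)
        assert f == pytest.approx(1.0 / prof.cycles["period_s"].mean(), abs=0.2)

    def test_white_noise_has_no_principal_frequency(self, rng):
        sig = TaskSignal(rng.normal(0, 1, 600), rate=100, task="FT")
        assert principal_frequency(sig) is None

    def test_short_signal_rejected(self):
        sig = TaskSignal(np.sin(np.arange(200) * 0.2), rate=100, task="FT")
        with pytest.raises(ValueError, match="3 s"):
            principal_frequency(sig)


class TestFeatures:
    def _cycles(self, amplitudes, durations=None):
        n = len(amplitudes)
        durations = durations if durations is not None else [0.5] * n
        return pd.DataFrame({
            "start": np.arange(n) * 50, "peak": np.arange(n) * 50 + 25,
            "end": (np.arange(n) + 1) * 50,
            "t_start": np.arange(n) * 0.5,
            "duration_s": durations,
            "open_duration_s": np.array(durations) / 2,
            "close_duration_s": np.array(durations) / 2,
            "max_opening": np.asarray(amplitudes) + 5.0,
            "amplitude": amplitudes,
            "max_speed_opening": np.asarray(amplitudes) * np.pi * 2,
            "max_speed_closing": np.asarray(amplitudes) * np.pi * 2,
        })

    def test_identical_cycles_have_zero_cv(self):
        f = compute_features(self._cycles([50.0, 50.0, 50.0]), task=TaskKind.OC)
        for name in ("MOSv", "MCSv", "MAv", "Dv"):
            assert f[name] == 0.0

    def test_known_amplitudes_hand_arithmetic(self):
        f = compute_features(self._cycles([40.0, 50.0, 60.0]), task=TaskKind.OC)
        assert f["MAm"] == pytest.approx(50.0)
        assert f["MAv"] == pytest.approx(np.std([40, 50, 60], ddof=1) / 50.0)

    def test_zero_mean_cv_is_nan_with_warning(self):
        cyc = self._cycles([1.0, -1.0])
        with pytest.warns(UserWarning, match="zero mean"):
            f = compute_features(cyc, task=TaskKind.OC)
        assert np.isnan(f["MAv"])

    def test_single_cycle_rejected(self):
        with pytest.raises(InsufficientCyclesError):
            compute_features(self._cycles([50.0]), task=TaskKind.OC)

    def test_feature_vector_complete_per_task(self):
        sigs = {t: _signal_from(t, A, 2.0, 8)
                for t, A in [("FT", 60.0), ("OC", 80.0), ("PS", 160.0)]}
        for task, sig in sigs.items():
            f = compute_features(segment_cycles(sig), sig)
            assert list(f.index) == FEATURES[TaskKind(task)]
            assert f.notna().all()

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(0.1, 10.0))
    def test_cv_features_scale_invariant(self, k):
        cyc = self._cycles([40.0, 55.0, 60.0], durations=[0.4, 0.5, 0.6])
        base = compute_features(cyc, task=TaskKind.OC)
        scaled_cyc = cyc.copy()
        for col in ("max_opening", "amplitude", "max_speed_opening", "max_speed_closing"):
            scaled_cyc[col] = cyc[col] * k
        scaled = compute_features(scaled_cyc, task=TaskKind.OC)
        for name in ("MOSv", "MCSv", "MAv", "Dv"):
            assert scaled[name] == pytest.approx(base[name], rel=1e-9)
        assert scaled["MAm"] == pytest.approx(k * base["MAm"], rel=1e-9)

    def test_injected_amplitude_variability_recovered(self):
        vals = []
        for seed in range(5):
            p = MotionParams(task="FT", base_amplitude=60, base_frequency=3, n_cycles=50,
                             amplitude_cv=0.2, noise_sd=1.0, seed=seed)
            sig = extract_task_signal(embed_in_3d(generate_scalar_profile(p)), rate=100)
            vals.append(compute_features(segment_cycles(sig), sig)["MAv"])
        assert np.mean(vals) == pytest.approx(0.2, abs=0.05)

    def test_decrement_lowers_mam_and_raises_mav(self):
        def feats(decr, seed):
            p = MotionParams(task="FT", base_amplitude=60, base_frequency=3, n_cycles=20,
                             decrement_rate=decr, noise_sd=1.0, seed=seed)
            sig = extract_task_signal(embed_in_3d(generate_scalar_profile(p)), rate=100)
            return compute_features(segment_cycles(sig), sig)
        lo = np.mean([[feats(0.0, s)["MAm"], feats(0.0, s)["MAv"]] for s in range(4)], axis=0)
        hi = np.mean([[feats(0.06, s)["MAm"], feats(0.06, s)["MAv"]] for s in range(4)], axis=0)
        assert hi[0] < lo[0] and hi[1] > lo[1]


def test_features_for_recording_full_chain(ft_recording):
    f = features_for_recording(ft_recording)
    assert f["MAm"] == pytest.approx(60.0, rel=0.02)
    assert f["Freq"] == pytest.approx(2.0, abs=0.1)
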