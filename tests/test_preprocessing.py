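"""DTW, filtering, normalization, centering and tapered concatenation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wristkin import (
    StudyDesign,
    TrialMeta,
    butterworth_lowpass,
    center_by_subject,
    dtw,
    generate_trial,
    resample_normalized,
    synchronize_repetitions,
    taper_concatenate,
)
from wristkin.kinematics import extract_joint_angles
from wristkin.preprocessing import (
    DataError,
    NormalizedTrial,
    normalize_trial,
    tukey_window,
    uncenter,
    warp_onto_reference,
)
from wristkin.synthetic import ConfigError


def brute_force_dtw(a, b):
    """Exhaustive enumeration of all monotone step paths (oracle)."""
    a = np.atleast_2d(np.asarray(a, float).T).T
    b = np.atleast_2d(np.asarray(b, float).T).T
    n, m = a.shape[0], b.shape[0]
    C = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    best = [np.inf]

    def walk(i, j, cost):
        cost += C[i, j]
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestDtw:
    def test_identical_series_cost_zero_diagonal_path(self):
        s = np.arange(5.0)
        cost, path = dtw(s, s)
        assert cost == 0.0
        assert path == [(i, i) for i in range(5)]

    def test_single_insertion(self):
        cost, path = dtw([0.0, 1.0, 2.0], [0.0, 1.0, 1.0, 2.0])
        assert cost == 0.0
        steps = {(i2 - i1, j2 - j1) for (i1, j1), (i2, j2) in zip(path, path[1:])}
        assert (0, 1) in steps  # one vertical (insertion) step

    def test_path_validity_and_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = rng.standard_normal(rng.integers(2, 9))
            b = rng.standard_normal(rng.integers(2, 9))
            ca, pa = dtw(a, b)
            cb, pb = dtw(b, a)
            assert ca == pytest.approx(cb, abs=1e-12)
            assert pa[0] == (0, 0) and pa[-1] == (len(a) - 1, len(b) - 1)
            diffs = {(i2 - i1, j2 - j1)
                     for (i1, j1), (i2, j2) in zip(pa, pa[1:])}
            assert diffs <= {(1, 0), (0, 1), (1, 1)}

    def test_matches_brute_force_oracle_exactly(self):
        """Acceptance-grade: DP equals exhaustive-path enumeration for all
        length pairs up to 7."""
        rng = np.random.default_rng(1)
        for n, m in itertools.product(range(1, 8), range(1, 8)):
            a = rng.standard_normal(n)
            b = rng.standard_normal(m)
            cost, _ = dtw(a, b)
            assert cost == pytest.approx(brute_force_dtw(a, b), abs=1e-12)

    def test_self_reversed_alignment_costs(self):
        s = np.linspace(0, 1, 20)
        cost, _ = dtw(s, s[::-1])
        assert cost > 0

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            dtw(np.empty(0), np.arange(3.0))


class TestSynchronize:
    def _extracted(self, seeds, jitter):
        design = StudyDesign(
            n_subjects=1, slots=("DL", "UR"), timing_jitter=jitter,
            pos_noise_cm=0.0, angle_noise_deg=0.0, repetition_noise_deg=0.0, path_noise_deg=0.0,
        )
        from wristkin import ArmModel

        model = ArmModel()
        out = []
        for rep, seed in enumerate(seeds, start=1):
            tr = generate_trial(model, design,
                                TrialMeta(0, "cylinder", "DL", "UR", rep), seed)
            out.append(extract_joint_angles(tr))
        return out

    def test_identical_repetitions_pass_through(self):
        group = self._extracted([3, 3, 3], jitter=0.0)
        synced = synchronize_repetitions(group)
        for ts in synced:
            assert ts.angles.shape == group[0].angles.shape
            assert np.allclose(ts.angles, group[0].angles, atol=1e-12)

    def test_alignment_reduces_rms_between_jittered_repetitions(self):
        group = self._extracted([1, 2, 3], jitter=0.15)
        n = min(ts.angles.shape[0] for ts in group)
        before = np.sqrt(np.mean((group[1].angles[:n] - group[0].angles[:n]) ** 2))
        synced = synchronize_repetitions(group)
        after = np.sqrt(np.mean((synced[1].angles - synced[0].angles) ** 2))
        assert after < before

    def test_single_repetition_warns(self):
        group = self._extracted([1], jitter=0.1)
        with pytest.warns(RuntimeWarning):
            synchronize_repetitions(group)

    def test_warp_averages_multiply_mapped_samples(self):
        path = [(0, 0), (0, 1), (1, 2), (2, 3)]
        vals = np.array([0.0, 2.0, 5.0, 9.0])
        out = warp_onto_reference(path, vals, 3)
        assert np.allclose(out, [1.0, 5.0, 9.0])


class TestButterworth:
    def test_dc_gain_unity(self):
        x = np.full(500, 3.7)
        for zp in (True, False):
            y = butterworth_lowpass(x, 5.0, 60.0, zero_phase=zp)
            assert np.max(np.abs(y - 3.7)) < 1e-9

    def test_single_pass_gain_at_cutoff(self):
        fs, fc = 200.0, 5.0
        t = np.arange(0, 60.0, 1.0 / fs)
        x = np.sin(2 * np.pi * fc * t)
        y = butterworth_lowpass(x, fc, fs, zero_phase=False)
        amp = np.ptp(y[len(y) // 3: 2 * len(y) // 3]) / 2
        assert amp == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_zero_phase_gain_and_lag(self):
        fs, fc = 200.0, 5.0
        t = np.arange(0, 60.0, 1.0 / fs)
        x = np.sin(2 * np.pi * fc * t)
        y = butterworth_lowpass(x, fc, fs, zero_phase=True)
        amp = np.ptp(y[len(y) // 3: 2 * len(y) // 3]) / 2
        assert amp == pytest.approx(0.5, rel=0.01)
        # zero lag: a low-frequency peak stays put
        x2 = np.sin(2 * np.pi * 0.5 * t)
        y2 = butterworth_lowpass(x2, fc, fs, zero_phase=True)
        sl = slice(0, int(fs))  # first cycle peak
        assert abs(int(np.argmax(y2[sl])) - int(np.argmax(x2[sl]))) <= 1

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            butterworth_lowpass(np.zeros(100), 40.0, 60.0)


class TestResample:
    def test_output_length_101(self):
        out = resample_normalized(np.random.default_rng(0).standard_normal(237))
        assert out.shape == (101,)

    def test_linear_ramp_exact(self):
        x = np.linspace(-3.0, 7.0, 240)
        out = resample_normalized(x)
        assert np.max(np.abs(out - np.linspace(-3.0, 7.0, 101))) < 1e-12

    def test_endpoints_preserved(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((57, 4))
        out = resample_normalized(x)
        assert np.array_equal(out[0], x[0]) and np.array_equal(out[-1], x[-1])


class TestNormalizeTrial:
    def test_filter_and_resample_distortion_bounded(self, noise_free_study):
        """Preprocessing a noise-free trial changes ground truth < 0.5 deg RMS."""
        ts = extract_joint_angles(noise_free_study[0])
        nt = normalize_trial(ts)
        truth = resample_normalized(noise_free_study[0].truth_angles)
        rms = np.sqrt(np.mean((nt.angles - truth) ** 2))
        assert rms < 0.5

    def test_wrong_sample_count_rejected(self):
        with pytest.raises(DataError):
            NormalizedTrial(
                meta=TrialMeta(0, "cylinder", "DL", "UR", 1),
                tau=np.linspace(0, 1, 50),
                angles=np.zeros((50, 9)),
                hand_pos=np.zeros((50, 3)),
            )


class TestCentering:
    def test_centered_subject_means_are_zero(self, small_centered):
        by_subject = {}
        for nt in small_centered:
            by_subject.setdefault(nt.meta.subject, []).append(nt.angles)
        for angles in by_subject.values():
            assert np.max(np.abs(np.vstack(angles).mean(axis=0))) < 1e-9

    def test_idempotent(self, small_centered):
        again, _ = center_by_subject(small_centered)
        for a, b in zip(again, small_centered):
            assert np.array_equal(a.angles, b.angles)

    def test_inverse_restores_originals(self, small_study):
        nts = [normalize_trial(extract_joint_angles(tr)) for tr in small_study]
        cen, _ = center_by_subject(nts)
        back = uncenter(cen)
        for orig, rec in zip(nts, back):
            assert np.max(np.abs(orig.angles - rec.angles)) < 1e-12


class TestTaperConcatenate:
    def test_window_shape(self):
        w = tukey_window(101, 5)
        assert w[0] == 0.0 and w[-1] == 0.0
        assert np.allclose(w[5:96], 1.0)

    def test_concatenation_layout(self, small_centered):
        angles, hand, bounds, order = taper_concatenate(small_centered[:2], 5, 0)
        assert angles.shape == (202, 9) and bounds == [0, 101]
        assert sorted(order) == [0, 1]

    def test_central_samples_unaltered_and_edges_zero(self, small_centered):
        nt = small_centered[0]
        angles, _, _, order = taper_concatenate([nt], 5)
        assert np.allclose(angles[5:96], nt.angles[5:96])
        assert np.allclose(angles[0], 0.0) and np.allclose(angles[100], 0.0)

    def test_oversized_taper_rejected(self, small_centered):
        with pytest.raises(ConfigError):
            taper_concatenate(small_centered[:1], taper_len=50)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(1, 20))
    def test_taper_length_controls_ramp(self, taper_len):
        w = tukey_window(101, taper_len)
        assert np.allclose(w[taper_len: 101 - taper_len], 1.0)
        if taper_len > 1:
            assert w[taper_len - 1] < 1.0
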