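"""Curve-resolution stage: baseline, windows, MCR-ALS, RI, IS, library."""

import numpy as np
import pandas as pd
import pytest

import predmet as pm
from predmet.resolution import (
    ResolvedFeature,
    make_toy_library,
    read_library,
    resolve_cube,
    spectral_cosine,
    write_library,
)
from predmet.simulate import RawDataCube


def _single_channel_cube(signal, n_samples=1, n_mz=10, channel=3):
    nt = len(signal)
    t = np.arange(nt) * 0.5
    inten = np.zeros((n_samples, nt, n_mz))
    inten[:, :, channel] = signal[None, :]
    markers = [(0.0, 1000.0), (t[-1], 1100.0)]
    return RawDataCube([f"s{i}" for i in range(n_samples)], t, np.arange(50, 50 + n_mz), inten, markers)


class TestBaselineCorrect:
    def test_constant_baseline_removed_entirely(self):
        cube = _single_channel_cube(np.full(100, 3.0), n_samples=2)
        out = pm.baseline_correct(cube, 21)
        assert np.abs(out.intensities).max() == 0.0

    def test_peak_apex_preserved(self):
        t = np.arange(100) * 0.5
        peak = 100 * np.exp(-0.5 * ((t - 25) / 1.5) ** 2)
        out = pm.baseline_correct(_single_channel_cube(peak), 31)
        assert out.intensities[0, :, 3].max() == pytest.approx(100, rel=0.05)

    def test_ramp_baseline_leaves_true_peak_area(self):
        t = np.arange(100) * 0.5
        peak = 100 * np.exp(-0.5 * ((t - 25) / 1.5) ** 2)
        ramp = np.linspace(0.0, 50.0, 100)
        out = pm.baseline_correct(_single_channel_cube(peak + ramp), 31)
        est = np.trapezoid(out.intensities[0, :, 3], t)
        assert est == pytest.approx(np.trapezoid(peak, t), rel=0.10)

    def test_tic_never_increases(self):
        cube, _ = pm.generate_cube(3, 2, 2, snr=30, baseline_drift=2.0, seed=1)
        out = pm.baseline_correct(cube, 21)
        assert (out.tic() <= cube.tic() + 1e-9).all()

    def test_parameter_errors(self):
        cube = _single_channel_cube(np.ones(50))
        with pytest.raises(ValueError):
            pm.baseline_correct(cube, 4)
        with pytest.raises(ValueError):
            pm.baseline_correct(cube, 999)


class TestSegmentWindows:
    def test_single_window_spans_axis(self):
        cube, _ = pm.generate_cube(3, 1, 1, seed=1)
        (w,) = pm.segment_windows(cube, 1)
        assert (w.start, w.end) == (0, len(cube.time_axis))

    def test_boundary_between_two_separated_peaks(self):
        cube, truth = pm.generate_cube(4, 2, 1, overlap=0.0, snr=200, seed=2)
        windows = pm.segment_windows(cube, 2, min_width=10)
        boundary_t = cube.time_axis[windows[0].end]
        apex = sorted(truth.component_elutions["center"])
        assert apex[0] < boundary_t < apex[1]

    def test_windows_tile_axis_half_open(self):
        cube, _ = pm.generate_cube(4, 4, 2, overlap=0.2, snr=100, seed=3)
        windows = pm.segment_windows(cube, 4, min_width=20)
        assert windows[0].start == 0
        assert windows[-1].end == len(cube.time_axis)
        for a, b in zip(windows[:-1], windows[1:]):
            assert a.end == b.start

    def test_each_window_holds_exactly_one_cluster(self):
        """On a multi-cluster chromatogram each segmented window contains one
        ground-truth peak cluster."""
        cube, truth = pm.generate_cube(6, 8, 2, overlap=0.3, snr=100, seed=4)
        windows = pm.segment_windows(cube, 8, min_width=10)
        centers = truth.component_elutions["center"].to_numpy()
        counts = []
        for w in windows:
            t0, t1 = cube.time_axis[w.start], cube.time_axis[w.end - 1]
            counts.append(((centers >= t0) & (centers <= t1)).sum())
        assert counts == [2] * 8  # 2 components per cluster, one cluster per window

    def test_too_many_windows_rejected(self):
        cube, _ = pm.generate_cube(3, 1, 1, seed=1)
        with pytest.raises(ValueError):
            pm.segment_windows(cube, 100, min_width=5)


class TestResolveWindow:
    def test_noise_free_single_component_exact(self):
        cube, truth = pm.generate_cube(2, 1, 1, snr=np.inf, seed=1)
        (w,) = pm.segment_windows(cube, 1)
        feats = pm.resolve_window(w)
        assert len(feats) == 1
        assert spectral_cosine(feats[0].spectrum, truth.component_spectra[0]) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_overlapping_components_recovered(self, seed, component_matcher):
        cube, truth = pm.generate_cube(8, 1, 2, overlap=0.5, snr=100, seed=seed)
        feats = pm.resolve_window(pm.segment_windows(cube, 1)[0])
        assert len(feats) == 2
        perm = component_matcher(feats, truth.component_spectra)
        for j in range(2):
            f = feats[perm[j]]
            assert spectral_cosine(f.spectrum, truth.component_spectra[j]) > 0.99
            rel = np.abs(f.areas.to_numpy() - truth.true_areas[:, j]) / truth.true_areas[:, j]
            assert rel.max() < 0.05

    def test_three_components_perfect_matching(self, component_matcher):
        cube, truth = pm.generate_cube(8, 1, 3, overlap=0.5, snr=100, seed=5)
        feats = pm.resolve_window(pm.segment_windows(cube, 1)[0])
        assert len(feats) == 3
        perm = component_matcher(feats, truth.component_spectra)
        assert len(set(perm)) == 3
        for j in range(3):
            assert spectral_cosine(feats[perm[j]].spectrum, truth.component_spectra[j]) > 0.95

    def test_all_zero_window_gives_empty_list(self):
        cube = _single_channel_cube(np.zeros(60))
        (w,) = pm.segment_windows(cube, 1)
        assert pm.resolve_window(w) == []

    def test_area_conservation_noise_free(self):
        """Component outer products reconstruct each sample's window matrix."""
        cube, _ = pm.generate_cube(5, 1, 2, overlap=0.4, snr=np.inf, seed=6)
        (w,) = pm.segment_windows(cube, 1)
        feats = pm.resolve_window(w)
        for i in range(5):
            recon = np.zeros_like(w.tensor[i])
            for f in feats:
                profile = f.elution_profile
                scale_i = f.areas.iloc[i] / np.trapezoid(profile, w.time)
                recon += scale_i * np.outer(profile, f.spectrum)
            err = np.linalg.norm(w.tensor[i] - recon) / np.linalg.norm(w.tensor[i])
            assert err < 0.01

    def test_snr_monotonicity_of_recovery(self, component_matcher):
        """Raising SNR never degrades the median recovery cosine."""
        medians = []
        for snr in (5.0, 50.0, 500.0):
            cosines = []
            for seed in range(3):
                cube, truth = pm.generate_cube(6, 1, 2, overlap=0.5, snr=snr, seed=seed)
                feats = pm.resolve_window(pm.segment_windows(cube, 1)[0], max_components=2)
                perm = component_matcher(feats, truth.component_spectra)
                cosines.extend(
                    spectral_cosine(feats[perm[j]].spectrum, truth.component_spectra[j])
                    for j in range(min(len(feats), 2))
                )
            medians.append(np.median(cosines))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9

    def test_sample_permutation_permutes_areas(self):
        cube, _ = pm.generate_cube(6, 1, 2, overlap=0.3, snr=200, seed=8)
        (w,) = pm.segment_windows(cube, 1)
        feats = pm.resolve_window(w)
        perm = [3, 1, 5, 0, 2, 4]
        w2 = pm.Window(0, w.start, w.end, w.tensor[perm], w.time, w.mz)
        feats2 = pm.resolve_window(w2)
        for f, f2 in zip(feats, feats2):
            np.testing.assert_allclose(
                f2.areas.to_numpy(), f.areas.to_numpy()[perm], rtol=1e-6
            )


class TestRetentionIndex:
    def _feature(self, apex):
        return ResolvedFeature(0, np.ones(3), np.ones(4) / 4, pd.Series([1.0]), apex_time=apex)

    def test_apex_at_marker(self):
        f = self._feature(10.0)
        assert pm.assign_retention_index(f, [(10.0, 1000.0), (20.0, 1100.0)]) == 1000.0

    def test_apex_midway(self):
        f = self._feature(15.0)
        assert pm.assign_retention_index(f, [(10.0, 1000.0), (20.0, 1100.0)]) == 1050.0

    def test_generator_ladder_closed_form(self):
        cube, truth = pm.generate_cube(2, 2, 1, snr=np.inf, seed=3)
        feats = [f for w in pm.segment_windows(cube, 2, min_width=20) for f in pm.resolve_window(w)]
        for f in feats:
            ri = pm.assign_retention_index(f, cube.ri_markers)
            # ladder: RI 1000 at t=0, +100 per 30 s window
            assert ri == pytest.approx(1000.0 + 100.0 * f.apex_time / 30.0, abs=1e-6)

    def test_extrapolation_flagged(self):
        f = self._feature(99.0)
        pm.assign_retention_index(f, [(10.0, 1000.0), (20.0, 1100.0)])
        assert f.ri_extrapolated


class TestNormalizeByIS:
    def _features(self, areas_matrix, sample_ids, is_rows):
        feats = []
        for j, areas in enumerate(areas_matrix):
            fid = f"IS{j}" if j in is_rows else f"F{j}"
            feats.append(
                ResolvedFeature(
                    0, np.ones(3), np.ones(4) / 4,
                    pd.Series(areas, index=sample_ids), apex_time=1.0, feature_id=fid,
                )
            )
        return feats

    def test_unit_is_leaves_areas_unchanged(self):
        sids = ["a", "b"]
        feats = self._features([[2.0, 3.0], [1.0, 1.0]], sids, is_rows={1})
        table = pm.normalize_by_is(feats, ["IS1"], sample_ids=sids)
        np.testing.assert_allclose(table.X["F0"].to_numpy(), [2.0, 3.0])

    def test_global_sample_scale_invariance(self):
        sids = ["a", "b"]
        feats = self._features([[2.0, 6.0], [5.0, 15.0], [1.0, 3.0]], sids, is_rows={2})
        table = pm.normalize_by_is(feats, ["IS2"], sample_ids=sids)
        np.testing.assert_allclose(table.X.loc["a"], table.X.loc["b"])

    def test_normalization_reduces_cv_of_null_features(self):
        cube, truth = pm.generate_cube(
            12, 3, 2, n_is=3, overlap=0.2, snr=200, seed=4, recovery_sd=0.25
        )
        is_names = [n for n in truth.feature_ids if n.startswith("IS")]
        ris = [1000 + 100 * c / 30.0 for c in truth.component_elutions["center"]]
        lib = make_toy_library(cube.mz_axis, truth.component_spectra, ris, truth.feature_ids)
        table, feats = resolve_cube(cube, 3, library=lib, is_names=is_names)
        raw = {f.putative_id[0]: f.areas.to_numpy() for f in feats if f.putative_id}
        cv_pre, cv_post = [], []
        for fid in table.X.columns:
            pid = table.feature_meta.loc[fid, "putative_id"]
            if pid in raw:
                pre, post = raw[pid], table.X[fid].to_numpy()
                cv_pre.append(pre.std() / pre.mean())
                cv_post.append(post.std() / post.mean())
        assert np.mean(cv_post) < np.mean(cv_pre)

    def test_failed_is_flags_sample(self):
        sids = ["a", "b"]
        feats = self._features([[2.0, 3.0], [1.0, 0.0]], sids, is_rows={1})
        table = pm.normalize_by_is(feats, ["IS1"], sample_ids=sids)
        assert list(table.sample_meta["is_failed"]) == [False, True]


class TestMatchLibrary:
    def _library_and_feature(self, seed=0):
        rng = np.random.default_rng(seed)
        mz = np.arange(50, 150)
        spec = np.zeros(100)
        spec[rng.choice(100, 12, replace=False)] = rng.uniform(0.1, 1, 12)
        spec /= spec.sum()
        lib = make_toy_library(mz, spec[None, :], [1500.0], ["target"], n_decoys=20, seed=seed + 1)
        feat = ResolvedFeature(0, np.ones(3), spec, pd.Series([1.0]), 5.0, retention_index=1500.0)
        return lib, feat, spec

    def test_identical_spectrum_scores_one(self):
        lib, feat, _ = self._library_and_feature()
        name, score = pm.match_library(feat, lib, min_score=0.8, ri_tol=30)
        assert name == "target" and score == pytest.approx(1.0)

    def test_ri_gate_blocks_identical_spectrum(self):
        lib, feat, _ = self._library_and_feature()
        feat.retention_index = 1700.0
        feat.putative_id = None
        # only the decoys are in RI tolerance now; none should clear min_score
        assert pm.match_library(feat, lib, min_score=0.9, ri_tol=30) is None

    def test_noisy_copy_beats_decoys(self):
        rng = np.random.default_rng(42)
        lib, feat, spec = self._library_and_feature(seed=3)
        noisy = spec + rng.normal(0, np.linalg.norm(spec) / (50 * np.sqrt(len(spec))), len(spec))
        feat.spectrum = np.clip(noisy, 0, None)
        # brute-force oracle: the target must hold the max cosine over all entries
        scores = {n: spectral_cosine(feat.spectrum, s) for n, s, _ in lib.entries}
        assert max(scores, key=scores.get) == "target"
        name, _ = pm.match_library(feat, lib, min_score=0.8, ri_tol=1e9)
        assert name == "target"

    def test_library_text_roundtrip(self, tmp_path):
        lib, _, _ = self._library_and_feature()
        write_library(lib, tmp_path / "lib.tsv")
        back = read_library(tmp_path / "lib.tsv", lib.mz)
        assert [e[0] for e in back.entries] == [e[0] for e in lib.entries]
        for (_, sa, ra), (_, sb, rb) in zip(lib.entries, back.entries):
            assert ra == pytest.approx(rb, abs=0.1)
            assert spectral_cosine(sa, sb) > 0.9999
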