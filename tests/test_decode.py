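"""CV harness, feature pipelines, virtual channels, leakage control."""

import numpy as np
import pytest

from megdigits.decode import (
    a_epoch_feature_builder,
    a_window_feature_builder,
    build_virtual_channels,
    cv_ovr_linear,
    decode_a_epoch,
    decode_a_window,
    decode_power,
    pca_feature_builder,
    pointwise_decode,
    single_vs_combined,
    windowwise_decode,
)
from megdigits.source import extrema_vertices
from megdigits.stats import cluster_permutation


def _blobs(rng, n_per_class=30, d=5, sep=10.0):
    X, y = [], []
    for k in range(4):
        c = np.zeros(d)
        c[k % d] = sep * (1 + k)
        X.append(c + rng.standard_normal((n_per_class, d)))
        y.append(np.full(n_per_class, k))
    return np.concatenate(X), np.concatenate(y)


class TestCvHarness:
    def test_separable_blobs_perfect(self, rng):
        X, y = _blobs(rng)
        res = cv_ovr_linear(X, y, seed=0)
        assert res.mean_accuracy == 1.0
        assert np.array_equal(res.confusion, np.diag([30] * 4))

    def test_permuted_labels_at_chance(self):
        """Uninformative features decode at the 25% chance level (95% CI)."""
        X = np.random.default_rng(3).standard_normal((400, 20))
        y = np.random.default_rng(4).permutation(np.repeat(np.arange(4), 100))
        res = cv_ovr_linear(X, y, seed=0)
        n = res.confusion.sum()
        assert n == 400
        assert abs(res.overall_accuracy - 0.25) < 1.96 * np.sqrt(0.25 * 0.75 / n)

    def test_feature_duplication_invariance(self, rng):
        X, y = _blobs(rng, sep=3.0)
        a = cv_ovr_linear(X, y, seed=1)
        b = cv_ovr_linear(np.hstack([X, X]), y, seed=1)
        assert abs(a.mean_accuracy - b.mean_accuracy) <= 0.05

    def test_confusion_row_sums_match_class_counts(self, rng):
        X, y = _blobs(rng, n_per_class=15, sep=1.0)
        res = cv_ovr_linear(X, y, seed=2)
        assert np.array_equal(res.confusion.sum(axis=1), np.full(4, 15))
        assert res.overall_accuracy == pytest.approx(
            np.trace(res.confusion) / res.confusion.sum()
        )

    def test_zero_variance_features_warn(self):
        X = np.zeros((40, 3))
        y = np.repeat(np.arange(4), 10)
        with pytest.warns(UserWarning, match="zero variance"):
            cv_ovr_linear(X, y, seed=0)

    def test_too_few_trials_per_class_rejected(self):
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 3, 3, 3, 3])
        with pytest.raises(ValueError, match="fewer than"):
            cv_ovr_linear(np.zeros((19, 2)), y, folds=5)

    def test_seed_reproducibility(self, rng):
        X, y = _blobs(rng, sep=1.5)
        a = cv_ovr_linear(X, y, seed=7)
        b = cv_ovr_linear(X, y, seed=7)
        assert np.array_equal(a.fold_accuracies, b.fold_accuracies)
        assert np.array_equal(a.confusion, b.confusion)

    def test_summary_mentions_accuracy(self, rng):
        X, y = _blobs(rng)
        s = cv_ovr_linear(X, y, seed=0).summary()
        assert "mean accuracy" in s and "chance" in s


class TestTimeResolved:
    def test_pointwise_series_length_and_peak(self, delta_dataset):
        res = pointwise_decode(delta_dataset["src"], decim=30, seed=0)
        assert res.series.size == delta_dataset["src"].n_samples // 30
        # delta signal peaks near movement onset; baseline region is at chance
        t_peak = res.series_times[np.argmax(res.series)]
        assert abs(t_peak) < 0.5
        base = res.series[res.series_times < -1.2]
        assert abs(base.mean() - 0.25) < 0.12

    def test_windowwise_sixty_entries(self, delta_dataset):
        res = windowwise_decode(delta_dataset["awin"], seed=0)
        assert res.series.size == 60
        assert res.series_folds.shape == (5, 60)
        w_peak = res.series_times[np.argmax(res.series)]
        assert abs(w_peak) <= 0.5

    def test_windowwise_requires_windowed_map(self, delta_dataset):
        with pytest.raises(ValueError):
            windowwise_decode(delta_dataset["amap"])


class TestSpatialPipelines:
    def test_feature_dimensionalities_match(self, delta_dataset):
        """A-window features match the A-epoch dimensionality: 8 vertices
        x 900 task samples = 60 windows x 8 vertices x 15 samples."""
        src = delta_dataset["src"]
        idx = np.arange(src.n_trials)
        b_ep = a_epoch_feature_builder(src, delta_dataset["amap"])
        b_win = a_window_feature_builder(src, delta_dataset["awin"])
        X_ep, _ = b_ep(idx, idx[:1])
        X_win, _ = b_win(idx, idx[:1])
        assert X_ep.shape[1] == 8 * 900
        assert X_win.shape[1] == X_ep.shape[1]

    def test_pca_feature_length(self, delta_dataset):
        src = delta_dataset["src"]
        idx = np.arange(src.n_trials)
        X_tr, X_te = pca_feature_builder(src, 0.70)(idx, idx[:2])
        assert X_tr.shape[1] % 900 == 0
        assert X_te.shape == (2, X_tr.shape[1])

    def test_pipelines_beat_chance_on_delta_signal(self, delta_dataset):
        from megdigits.decode import decode_pca

        src = delta_dataset["src"]
        sd3 = 3 * np.sqrt(0.25 * 0.75 / src.n_trials)
        results = [
            decode_pca(src, seed=0),
            decode_a_epoch(src, delta_dataset["amap"], seed=0),
            decode_a_window(src, delta_dataset["awin"], seed=0),
        ]
        for res in results:
            assert res.mean_accuracy > 0.25 + sd3

    def test_no_leakage_from_test_trials(self, delta_dataset):
        """Perturbing test-fold trials leaves the training-fold features
        (extrema selection, PCA loadings, scaling inputs) unchanged."""
        src = delta_dataset["src"]
        idx = np.arange(src.n_trials)
        tr, te = idx[:80], idx[80:]
        for builder_fn in (
            lambda s: pca_feature_builder(s, 0.70),
            lambda s: a_epoch_feature_builder(s, delta_dataset["amap"]),
            lambda s: a_window_feature_builder(s, delta_dataset["awin"]),
        ):
            X_tr1, _ = builder_fn(src)(tr, te)
            corrupted = src.copy()
            corrupted.data[te] += 1e3 * np.random.default_rng(0).standard_normal(
                corrupted.data[te].shape
            )
            X_tr2, _ = builder_fn(corrupted)(tr, te)
            assert np.array_equal(X_tr1, X_tr2)

    def test_power_features_beat_chance(self, delta_dataset):
        res = decode_power(
            delta_dataset["src"],
            delta_dataset["amap"],
            freqs=np.array([2.0, 3.0]),
            decim=10,
            seed=0,
        )
        n = delta_dataset["src"].n_trials
        assert res.mean_accuracy > 0.25 + 3 * np.sqrt(0.25 * 0.75 / n)


@pytest.fixture(scope="module")
def vc_setup(delta_dataset):
    src = delta_dataset["src"]
    awin = delta_dataset["awin"]
    ww = windowwise_decode(awin, seed=0)
    pw = pointwise_decode(src, decim=10, seed=0)
    cw = cluster_permutation(ww.series_folds, null_value=0.25, n_perm=500, tail=1, seed=3)
    ww.significant_spans = cw.significant_spans(ww.series_times)
    cp = cluster_permutation(pw.series_folds, null_value=0.25, n_perm=500, tail=1, seed=3)
    pw.significant_spans = cp.significant_spans(pw.series_times)
    ext = extrema_vertices(awin)
    vcs = build_virtual_channels(ww, pw, ext, awin.window_starts, 0.05)
    return {"src": src, "ww": ww, "pw": pw, "ext": ext, "vcs": vcs, "awin": awin}


class TestVirtualChannels:
    def test_entry_count_is_windows_times_eight(self, vc_setup):
        vcs = vc_setup["vcs"]
        assert len(vcs.entries) == vcs.decodable_windows.size * 8
        assert not vcs.empty
        # delta signal: decodable windows cluster around movement onset
        starts = vc_setup["awin"].window_starts[vcs.decodable_windows]
        assert starts.min() > -1.0 and starts.max() < 1.5

    def test_missing_spans_rejected(self, vc_setup):
        ww = windowwise_decode(vc_setup["awin"], seed=0)  # spans not set
        with pytest.raises(ValueError, match="significance spans"):
            build_virtual_channels(
                ww, vc_setup["pw"], vc_setup["ext"],
                vc_setup["awin"].window_starts, 0.05,
            )

    def test_single_window_equals_combined(self, vc_setup):
        """With exactly one decodable window the combined scheme reduces to
        the single-window scheme."""
        from megdigits.containers import VirtualChannelSet

        vcs = vc_setup["vcs"]
        w0 = int(vcs.decodable_windows[0])
        one = VirtualChannelSet(
            entries=[e for e in vcs.entries if e[0] == w0],
            decodable_windows=np.array([w0]),
            decodable_timespans=vcs.decodable_timespans,
            window_starts=vcs.window_starts,
            window_length=vcs.window_length,
        )
        singles, combined = single_vs_combined(vc_setup["src"], one, seed=0)
        assert set(singles) == {w0}
        assert combined.mean_accuracy == singles[w0].mean_accuracy

    def test_combined_at_least_best_single(self, vc_setup):
        singles, combined = single_vs_combined(vc_setup["src"], vc_setup["vcs"], seed=0)
        assert len(singles) == vc_setup["vcs"].decodable_windows.size
        best = max(r.mean_accuracy for r in singles.values())
        assert combined.mean_accuracy >= best - 0.05

    def test_empty_set_flagged(self, vc_setup):
        from megdigits.containers import VirtualChannelSet

        empty = VirtualChannelSet(
            entries=[], decodable_windows=np.array([], dtype=int),
            decodable_timespans=[],
        )
        with pytest.warns(UserWarning, match="empty"):
            singles, combined = single_vs_combined(vc_setup["src"], empty, seed=0)
        assert singles == {} and combined is None
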