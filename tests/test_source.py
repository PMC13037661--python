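"""Beamformer, activation-index maps, extrema selection and ROI PCA."""

import numpy as np
import pytest

from megdigits.containers import ActivationMap, Epochs, SourceModel
from megdigits.source import (
    a_window_maps,
    activation_index,
    activation_index_from_cov,
    data_covariance,
    extrema_vertices,
    fit_lcmv,
    reconstruct,
    roi_pca,
)
from megdigits.synth import SimulationConfig, make_source_model, simulate_meg


def _epochs(data, sfreq=300.0, t0=-2.0):
    labels = np.arange(data.shape[0]) % 4
    return Epochs(data=np.asarray(data, float), sfreq=sfreq, t0=t0, labels=labels)


class TestDataCovariance:
    def test_white_noise_near_identity(self, rng):
        x = rng.standard_normal((10, 8, 12500))  # 1e5 pooled samples
        cov = data_covariance(_epochs(x))
        off = cov - np.diag(np.diag(cov))
        assert np.abs(np.diag(cov) - 1).max() < 0.05
        assert np.abs(off).max() < 0.05

    def test_rank_one_data(self, rng):
        u = rng.standard_normal(6)
        s = rng.standard_normal((4, 1, 200))
        x = u[None, :, None] * s
        cov = data_covariance(_epochs(x))
        ev = np.linalg.eigvalsh(cov)[::-1]
        assert ev[0] > 1e8 * max(abs(ev[1]), 1e-300)

    def test_duplicated_trials_identical(self, rng):
        x = rng.standard_normal((3, 5, 100))
        c1 = data_covariance(_epochs(x))
        c2 = data_covariance(_epochs(np.concatenate([x, x])))
        # doubling every trial leaves the pooled covariance unchanged up to
        # the (n-1) normalizer
        n1 = 3 * 100 - 1
        n2 = 6 * 100 - 1
        assert np.allclose(c1 * n1 * 2, c2 * n2, rtol=1e-10)

    def test_nan_rejected(self):
        x = np.zeros((2, 3, 50))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            data_covariance(_epochs(x))


class TestFitLcmv:
    def test_unit_gain_for_every_vertex(self, delta_dataset):
        fit = delta_dataset["fit"]
        model = delta_dataset["model"]
        for v in range(model.n_vertices):
            l_eff = model.leadfield_free[:, v, :] @ fit.orientation[v]
            assert abs(fit.weights[v] @ l_eff - 1.0) < 1e-6

    def test_identity_covariance_matches_pseudoinverse(self):
        """With C = I (and no loading) the LCMV weight row equals
        l / (l^T l): the least-norm unit-gain filter."""
        m = make_source_model(10, 16, seed=4)
        fit = fit_lcmv(m, np.eye(16), reg=0.0)
        for v in range(3):
            l_eff = m.leadfield_free[:, v, :] @ fit.orientation[v]
            expected = l_eff / (l_eff @ l_eff)
            assert np.allclose(fit.weights[v], expected, rtol=1e-8)

    def test_leadfield_scaling_inverts_weights(self):
        """Scaling a leadfield column by c scales the weight row by 1/c."""
        m = make_source_model(8, 16, seed=5)
        cov = np.eye(16) * 2.0
        fit1 = fit_lcmv(m, cov, reg=0.0)
        scaled = SourceModel(
            vertex_positions=m.vertex_positions,
            vertex_orientations=m.vertex_orientations,
            leadfield=m.leadfield * 3.0,
            leadfield_free=m.leadfield_free * 3.0,
        )
        fit3 = fit_lcmv(scaled, cov, reg=0.0)
        assert np.allclose(fit3.weights, fit1.weights / 3.0, rtol=1e-8)

    def test_singular_covariance_needs_loading(self):
        m = make_source_model(5, 16, seed=6)
        cov = np.zeros((16, 16))
        cov[0, 0] = 1.0
        with pytest.raises(np.linalg.LinAlgError, match="reg"):
            fit_lcmv(m, cov, reg=0.0)

    def test_point_source_localized(self):
        """A high-SNR point source is recovered at (or adjacent to) the
        generating vertex by reconstructed task-window variance."""
        m = make_source_model(100, 32, seed=11)
        cfg = SimulationConfig(
            n_trials_per_task=5,
            snr=50.0,
            cluster_size=1,
            amplitudes={"delta": 1.0, "background": 0.05},
        )
        ep, truth = simulate_meg(m, cfg, seed=12)
        fit = fit_lcmv(m, data_covariance(ep), reg=0.05)
        src = reconstruct(ep, fit)
        tw = ep.time_mask((-1.0, 2.0))
        for task in range(4):
            v_true = truth.active_vertex_sets[(task, "delta")][0]
            tr = np.flatnonzero(truth.task_labels == task)
            v_hat = int(np.argmax(src.data[tr][:, :, tw].var(axis=2).mean(axis=0)))
            assert v_hat in m.neighborhood(v_true, 0.05)


class TestReconstruct:
    def test_linearity_and_zero(self, delta_dataset):
        fit = delta_dataset["fit"]
        ep = delta_dataset["band"]
        a = reconstruct(ep, fit)
        b = reconstruct(ep.copy(data=2 * ep.data), fit)
        assert np.allclose(b.data, 2 * a.data, rtol=1e-12)
        z = reconstruct(ep.copy(data=np.zeros_like(ep.data)), fit)
        assert np.all(z.data == 0)

    def test_channel_mismatch_raises(self, delta_dataset):
        fit = delta_dataset["fit"]
        bad = _epochs(np.zeros((2, 7, 1200)))
        with pytest.raises(ValueError, match="mismatch"):
            reconstruct(bad, fit)

    def test_noise_free_source_time_course_recovered(self):
        m = make_source_model(40, 32, seed=13)
        cfg = SimulationConfig(
            n_trials_per_task=2,
            snr=np.inf,
            cluster_size=1,
            amplitudes={"delta": 1.0, "background": 0.0},
            task_vertices={k: [7] for k in range(4)},
        )
        ep, truth = simulate_meg(m, cfg, seed=14)
        fit = fit_lcmv(m, data_covariance(ep), reg=0.001)
        src = reconstruct(ep, fit)
        # reconstructed series at the true vertex matches the generating
        # course up to sign (orientation ambiguity)
        sensor_trial = ep.data[0]
        # infer the generating course from the rank-1 sensor data
        u, s, vt = np.linalg.svd(sensor_trial, full_matrices=False)
        gen = vt[0]
        rec = src.data[0, 7]
        r = np.corrcoef(rec, gen)[0, 1]
        assert abs(r) > 0.99


class TestActivationIndex:
    def test_hand_computed_quadratic_forms(self):
        """w=[1,0], Cs=diag(4,1), Cb=I: A = (4-1)/(4+1) = 0.6 exactly."""
        a = activation_index_from_cov(
            np.array([1.0, 0.0]), np.diag([4.0, 1.0]), np.eye(2)
        )
        assert a == pytest.approx(0.6, abs=1e-15)

    def test_equal_covariances_give_zero(self, rng):
        c = rng.standard_normal((4, 4))
        c = c @ c.T
        w = rng.standard_normal(4)
        assert activation_index_from_cov(w, c, c) == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_is_nan(self):
        z = np.zeros((2, 2))
        assert np.isnan(activation_index_from_cov(np.ones(2), z, z))

    def test_window_swap_negates_map(self, delta_dataset):
        fit = delta_dataset["fit"]
        ep = delta_dataset["band"]
        fwd = activation_index(fit, ep, (-1.0, 2.0), (-2.0, -1.5))
        rev = activation_index(fit, ep, (-2.0, -1.5), (-1.0, 2.0))
        assert np.allclose(fwd.trial_values, -rev.trial_values, rtol=1e-10)

    def test_bounds_and_trial_average(self, delta_dataset):
        amap = delta_dataset["amap"]
        assert np.all(np.abs(amap.trial_values) < 1.0)
        assert np.all(amap.values <= np.nanmax(amap.trial_values))
        assert np.all(amap.values >= np.nanmin(amap.trial_values))

    def test_matches_explicit_quadratic_form(self, delta_dataset):
        """The epochs path equals w Cs w^T etc. computed directly from the
        sensor windows (independent route) to near machine precision."""
        fit = delta_dataset["fit"]
        ep = delta_dataset["band"]
        amap = delta_dataset["amap"]
        ms = ep.time_mask((-1.0, 2.0))
        mb = ep.time_mask((-2.0, -1.5))
        for trial in (0, 5):
            for v in (0, 17, 42):
                w = fit.weights[v]
                vals = []
                for mask in (ms, mb):
                    seg = ep.data[trial][:, mask]
                    seg = seg - seg.mean(axis=1, keepdims=True)
                    vals.append(seg @ seg.T / seg.shape[1])
                expected = activation_index_from_cov(w, vals[0], vals[1])
                assert amap.trial_values[trial, v] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_window_outside_epoch_rejected(self, delta_dataset):
        with pytest.raises(ValueError):
            activation_index(
                delta_dataset["fit"], delta_dataset["band"], (-1.0, 2.0), (3.0, 4.0)
            )


class TestAWindowMaps:
    def test_sixty_windows_fifteen_samples(self, delta_dataset):
        awin = delta_dataset["awin"]
        assert awin.values.shape[2] == 60
        assert awin.window_starts[0] == pytest.approx(-1.0)
        assert awin.window_starts[-1] == pytest.approx(1.95)
        spw = awin.window_length * delta_dataset["band"].sfreq
        assert spw == pytest.approx(15.0)

    def test_non_integer_window_rejected(self, delta_dataset):
        with pytest.raises(ValueError):
            a_window_maps(delta_dataset["fit"], delta_dataset["band"], window=0.0513)

    def test_stationary_input_flat_across_windows(self, rng):
        """Stationary noise gives near-equal trial-averaged A in every window."""
        m = make_source_model(10, 16, seed=21, forward="random")
        x = rng.standard_normal((40, 16, 1200))
        ep = _epochs(x)
        fit = fit_lcmv(m, data_covariance(ep), reg=0.05)
        awin = a_window_maps(fit, ep)
        spread = awin.values.std(axis=2).max()
        # 15-sample windows over 100 trials: generous sampling-noise bound
        assert spread < 0.1

    def test_delta_bump_window_peaks_at_cluster(self, delta_dataset):
        """In the window covering the bump peak the map maximum falls in the
        generating cluster's neighbourhood."""
        awin = delta_dataset["awin"]
        model = delta_dataset["model"]
        truth = delta_dataset["truth"]
        w0 = int(np.argmin(np.abs(awin.window_starts - (-0.025))))
        for task in range(4):
            cluster = truth.active_vertex_sets[(task, "delta")]
            nb = set()
            for v in cluster:
                nb.update(model.neighborhood(v, 0.1))
            v_hat = int(np.nanargmax(awin.values[task, :, w0]))
            assert v_hat in nb


class TestExtremaVertices:
    def test_constructed_argmax_argmin(self):
        vals = np.zeros((4, 10))
        for k in range(4):
            vals[k, k] = 1.0
            vals[k, 9 - k] = -1.0
        ext = extrema_vertices(vals)
        assert ext.shape == (4, 2)
        assert [e[0] for e in ext] == [0, 1, 2, 3]
        assert [e[1] for e in ext] == [9, 8, 7, 6]

    def test_tie_breaks_to_lowest_index(self):
        vals = np.zeros((4, 6))
        ext = extrema_vertices(vals)
        assert np.all(ext == 0)

    def test_windowed_shape_eight_per_window(self, delta_dataset):
        ext = extrema_vertices(delta_dataset["awin"])
        assert ext.shape == (60, 4, 2)  # 8 vertices per window

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            extrema_vertices(np.full((4, 5), np.nan))


class TestRoiPca:
    def test_rank_one_single_component(self, rng):
        u = rng.standard_normal(12)
        s = rng.standard_normal((6, 1, 80))
        ep = _epochs(u[None, :, None] * s)
        comps, scores, evr = roi_pca(ep, var_frac=0.70)
        assert comps.shape == (1, 12)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)
        assert scores.shape == (6, 1, 80)

    def test_var_frac_validated(self, rng):
        ep = _epochs(rng.standard_normal((2, 4, 50)))
        with pytest.raises(ValueError):
            roi_pca(ep, var_frac=0.0)
        with pytest.raises(ValueError):
            roi_pca(ep, var_frac=1.5)

    def test_retained_variance_exceeds_threshold(self, delta_dataset):
        src = delta_dataset["src"]
        comps, scores, evr = roi_pca(src, var_frac=0.70)
        assert evr.sum() > 0.70

    def test_isotropic_noise_needs_most_components(self, rng):
        """Flat eigenspectrum: ~70% of the vertex count is retained."""
        ep = _epochs(rng.standard_normal((30, 40, 500)))
        comps, _, _ = roi_pca(ep, var_frac=0.70)
        assert abs(comps.shape[0] / 40 - 0.70) < 0.10
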