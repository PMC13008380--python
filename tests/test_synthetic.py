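"""Synthetic cohort generator: ground-truth structure and determinism."""

import numpy as np
import pandas as pd
import pytest

import couplingbench as cb
from couplingbench.prep import compute_fd
from couplingbench.synthetic import (
    Cohort,
    CohortSpec,
    distance_susceptibility,
    generate_behavior,
    inject_motion_artifact,
    make_true_network,
    read_cohort_arrays,
    simulate_motion,
    simulate_subject_series,
    write_cohort,
)


class TestMakeTrueNetwork:
    def test_zero_density_gives_diagonal_system(self):
        net = make_true_network(6, 0.0, 3)
        off = ~np.eye(6, dtype=bool)
        assert np.all(net.coupling_coefficients[off] == 0)
        sigma = net.stationary_covariance()
        assert np.allclose(sigma, np.diag(np.diag(sigma)))

    def test_stationary_covariance_solves_lyapunov(self):
        net = make_true_network(10, 0.3, 4)
        sigma = net.stationary_covariance()
        a, q = net.coupling_coefficients, net.innovation_covariance
        assert np.max(np.abs(sigma - a @ sigma @ a.T - q)) < 1e-8
        # SPD
        assert np.linalg.eigvalsh(sigma)[0] > 0

    def test_same_seed_bit_identical(self):
        n1 = make_true_network(7, 0.2, 42)
        n2 = make_true_network(7, 0.2, 42)
        assert np.array_equal(n1.coupling_coefficients, n2.coupling_coefficients)
        assert np.array_equal(n1.centroids, n2.centroids)

    def test_stability_enforced(self):
        for seed in range(5):
            net = make_true_network(20, 0.8, seed)
            rho = np.max(np.abs(np.linalg.eigvals(net.coupling_coefficients)))
            assert rho < 1.0

    def test_empirical_latent_covariance_matches_lyapunov(self):
        """Long simulated latent series reproduces the Lyapunov solution."""
        net = make_true_network(5, 0.3, 9)
        a, q = net.coupling_coefficients, net.innovation_covariance
        rng = np.random.default_rng(0)
        chol = np.linalg.cholesky(q)
        x = np.zeros(5)
        samples = np.empty((60000, 5))
        for t in range(60500):
            x = a @ x + chol @ rng.standard_normal(5)
            if t >= 500:
                samples[t - 500] = x
        emp = np.cov(samples, rowvar=False)
        sigma = net.stationary_covariance()
        assert np.max(np.abs(emp - sigma)) < 0.1 * np.max(np.abs(sigma))


class TestSimulateSubjectSeries:
    def test_zero_innovations_and_noise_give_constant_series(self):
        net = cb.TrueNetwork(0.5 * np.eye(3), np.zeros((3, 3)), np.zeros((3, 3)))
        s = simulate_subject_series(net, 100, 0.72, 1, noise_sd=0.0)
        assert np.allclose(s.data, s.data[0])

    def test_deterministic_in_seed(self, small_network):
        s1 = simulate_subject_series(small_network, 128, 0.72, 5)
        s2 = simulate_subject_series(small_network, 128, 0.72, 5)
        assert np.array_equal(s1.data, s2.data)

    def test_unstable_network_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            cb.TrueNetwork(1.2 * np.eye(3), np.eye(3), np.zeros((3, 3)))

    def test_lagged_cross_correlation_matches_planted_sign(self):
        """Monte-Carlo: a planted x->y coupling leaves a positive lagged
        cross-correlation asymmetry in nearly all replicates."""
        a = np.array([[0.5, 0.0], [0.4, 0.5]])
        net = cb.TrueNetwork(a, np.eye(2), np.zeros((2, 3)))
        hits = 0
        reps = 100
        for rep in range(reps):
            s = simulate_subject_series(net, 2000, 0.72, 100 + rep, noise_sd=0.1)
            x, y = s.data[:, 0], s.data[:, 1]
            asym = (
                np.corrcoef(x[:-1], y[1:])[0, 1]
                - np.corrcoef(y[:-1], x[1:])[0, 1]
            )
            hits += asym > 0
        assert hits / reps >= 0.95


class TestSimulateMotion:
    def test_zero_severity_all_zero(self):
        m = simulate_motion(200, 0.72, 0.0, 1)
        assert np.all(m.params == 0)
        assert np.all(compute_fd(m, apply_notch=False).fd_mm == 0)

    def test_mean_fd_matches_requested_severity(self):
        m = simulate_motion(1000, 0.72, 0.3, 7)
        fd = compute_fd(m, apply_notch=False)
        assert abs(fd.mean_fd - 0.3) < 0.2 * 0.3

    def test_respiratory_peak_in_band(self):
        from scipy import signal

        m = simulate_motion(1000, 0.72, 0.3, 7)
        f, pxx = signal.periodogram(m.params[:, 0], fs=1 / 0.72)
        mask = f > 0.05  # skip the AR(1) drift peak at low frequency
        peak = f[mask][np.argmax(pxx[mask])]
        assert 0.31 <= peak <= 0.43


class TestInjectMotionArtifact:
    def test_zero_gain_identity(self, subject_series):
        sus = distance_susceptibility(np.random.default_rng(0).uniform(
            0, 140, (subject_series.n_regions, 3)), 35.0)
        fd = np.abs(np.random.default_rng(1).standard_normal(
            subject_series.n_frames))
        out = inject_motion_artifact(subject_series, fd, sus, 0.0)
        assert out is subject_series

    def test_zero_susceptibility_identity(self, subject_series):
        fd = np.abs(np.random.default_rng(1).standard_normal(
            subject_series.n_frames))
        sus = np.zeros((subject_series.n_regions, subject_series.n_regions))
        out = inject_motion_artifact(subject_series, fd, sus, 1.0)
        assert out is subject_series

    def test_length_mismatch_raises(self, subject_series):
        sus = np.ones((subject_series.n_regions, subject_series.n_regions))
        with pytest.raises(ValueError, match="length"):
            inject_motion_artifact(subject_series, np.zeros(10), sus, 1.0)

    def test_group_design_produces_positive_qcfc_on_susceptible_edges(self):
        """High- vs zero-severity groups: Pearson FC on short edges
        correlates positively with mean FD across subjects."""
        from couplingbench.covariance import pearson_fc
        from couplingbench.qcfc import qcfc_correlations
        from couplingbench.types import stack_matrices

        net = make_true_network(10, 0.1, 2)
        sus = distance_susceptibility(net.centroids, 30.0)
        mats, fds = [], []
        for s in range(200):
            sev = 0.35 if s % 2 == 0 else 0.0
            rng = np.random.default_rng(4000 + s)
            ts = simulate_subject_series(net, 256, 0.72, rng, subject_id=f"s{s}")
            mot = simulate_motion(256, 0.72, sev, rng, subject_id=f"s{s}")
            fd = compute_fd(mot, apply_notch=False)
            mats.append(pearson_fc(inject_motion_artifact(ts, fd.fd_mm, sus, 1.0)))
            fds.append(fd.mean_fd)
        stack = stack_matrices(mats)
        res = qcfc_correlations(stack, np.array(fds))
        sus_vec = np.array([sus[i, j] for i, j in stack.edge_index])
        top = sus_vec >= np.quantile(sus_vec, 2 / 3)
        assert np.nanmean(res.qcfc[top]) > 0.1


class TestGenerateBehavior:
    def _covs(self, n, rng):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "site": "A",
                "family_id": [f"f{i}" for i in range(n)],
                "age": rng.uniform(9, 40, n),
                "sex": rng.integers(0, 2, n),
                "mean_fd": rng.uniform(0.05, 0.3, n),
            }
        )

    def test_null_effect_independent(self, rng):
        n = 2000
        score = rng.standard_normal((n, 1))
        beh = generate_behavior(score, 0.0, self._covs(n, rng), rng)
        r = np.corrcoef(beh["beh_00"], score[:, 0])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_planted_effect_recovered(self, rng):
        n = 2000
        score = rng.standard_normal((n, 1))
        beh = generate_behavior(score, 0.5, self._covs(n, rng), rng)
        r = np.corrcoef(beh["beh_00"], score[:, 0])[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_deterministic(self):
        rng_c = np.random.default_rng(5)
        covs = self._covs(50, rng_c)
        score = np.random.default_rng(6).standard_normal((50, 1))
        b1 = generate_behavior(score, 0.3, covs, 77)
        b2 = generate_behavior(score, 0.3, covs, 77)
        pd.testing.assert_frame_equal(b1, b2)


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(
        n_subjects=4, n_regions=5, n_frames=80, tr_s=0.8,
        n_sites=2, site_offset_sd=0.1, family_sizes=[2, 1, 1],
        rng_seed=3,
    )
    return cb.generate_cohort(spec)


class TestCohortRoundTrip:
    def test_cohort_deterministic(self, cohort):
        c2 = cb.generate_cohort(cohort.spec)
        for a, b in zip(cohort.series, c2.series):
            assert np.array_equal(a.data, b.data)
        pd.testing.assert_frame_equal(cohort.behavior, c2.behavior)

    def test_round_trip_bit_exact(self, cohort, tmp_path):
        write_cohort(cohort, tmp_path)
        back = read_cohort_arrays(tmp_path)
        for orig, rt in zip(cohort.series, back["series"]):
            assert np.array_equal(orig.data, rt.data)
        for orig, rt in zip(cohort.motion, back["motion"]):
            assert np.array_equal(orig.params, rt.params)
        assert np.array_equal(cohort.centroids, back["centroids"])

    def test_manifest_file_count(self, cohort, tmp_path):
        manifest = write_cohort(cohort, tmp_path)
        assert len(manifest["files"]) == cohort.spec.n_subjects * 2 + 3

    def test_checksum_detects_edit(self, cohort, tmp_path):
        write_cohort(cohort, tmp_path)
        victim = tmp_path / "behavior.csv"
        victim.write_text(victim.read_text() + "\n# tampered")
        with pytest.raises(ValueError, match="checksum"):
            read_cohort_arrays(tmp_path)
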