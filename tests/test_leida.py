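"""Hilbert phases, phase coherence, leading eigenvectors and the FCD matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dynconn.leida import (
    EigenvectorSeries,
    fcd_matrix,
    hilbert_phase,
    leading_eigenvector,
    leida_cohort_analysis,
    outer_pattern,
    phase_coherence_matrix,
    subject_eigenvectors,
)
from dynconn.prep import NetworkTimecourses
from dynconn.synthetic import generate_phase_coupled


def cosine_tc(freq_hz=0.05, T=290, tr=2.072, n_cols=1, phase=0.0):
    t = np.arange(T) * tr
    data = np.column_stack(
        [np.cos(2 * np.pi * freq_hz * t + phase) for _ in range(n_cols)]
    )
    return NetworkTimecourses("sub-cos", data, tr)


class TestHilbertPhase:
    def test_cosine_phase_advances_at_signal_frequency(self):
        freq, tr = 0.05, 2.072
        tc = cosine_tc(freq, T=290, tr=tr)
        ph = hilbert_phase(tc, drop_edges=1)
        mid = slice(100, 180)
        increments = np.diff(np.unwrap(ph.theta[:, 0]))[mid]
        expected = 2 * np.pi * freq * tr
        assert np.max(np.abs(increments - expected)) / expected < 0.01

    def test_quadrature_pair_phase_difference(self):
        t = np.arange(290) * 2.072
        omega = 2 * np.pi * 0.05
        data = np.column_stack([np.cos(omega * t), np.sin(omega * t)])
        ph = hilbert_phase(NetworkTimecourses("s", data, 2.072), drop_edges=1)
        diff = np.angle(np.exp(1j * (ph.theta[:, 0] - ph.theta[:, 1])))
        interior = diff[100:180]
        np.testing.assert_allclose(interior, np.pi / 2, atol=0.02)

    def test_drop_edges_zero_keeps_all_volumes(self):
        tc = cosine_tc(T=64)
        assert hilbert_phase(tc, drop_edges=0).theta.shape[0] == 64

    def test_constant_column_rejected(self):
        data = np.column_stack([np.ones(50), np.sin(np.arange(50.0))])
        with pytest.raises(ValueError, match="column 1"):
            hilbert_phase(NetworkTimecourses("s", data, 2.0))


class TestPhaseCoherence:
    def test_limit_values(self):
        theta = np.array([0.3, 0.3, 0.3 + np.pi / 2, 0.3 + np.pi])
        d = phase_coherence_matrix(theta)
        assert abs(d[0, 1] - 1.0) < 1e-12  # aligned
        assert abs(d[0, 2]) < 1e-12  # orthogonal
        assert abs(d[0, 3] + 1.0) < 1e-12  # antiphase
        np.testing.assert_allclose(np.diag(d), 1.0, atol=1e-15)
        np.testing.assert_allclose(d, d.T, atol=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(theta=arrays(float, st.integers(2, 8),
                        elements=st.floats(-np.pi, np.pi)))
    def test_trace_equals_n_and_entries_bounded(self, theta):
        d = phase_coherence_matrix(theta)
        assert abs(np.trace(d) - len(theta)) < 1e-9
        assert np.all(d >= -1 - 1e-12) and np.all(d <= 1 + 1e-12)
        # eigenvalues sum to the trace = N
        assert abs(np.linalg.eigvalsh(d).sum() - len(theta)) < 1e-8


class TestLeadingEigenvector:
    def test_fully_synchronised_rank_one_matrix(self):
        d = np.ones((4, 4))
        v = leading_eigenvector(d)
        np.testing.assert_allclose(v, -0.5 * np.ones(4), atol=1e-12)
        # top eigenvalue equals N for full synchrony
        assert abs(np.linalg.eigvalsh(d)[-1] - 4.0) < 1e-12

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            A = rng.normal(size=(6, 6))
            S = (A + A.T) / 2
            v = leading_eigenvector(S)
            vals, vecs = np.linalg.eig(S)
            top = vecs[:, np.argmax(vals.real)].real
            top /= np.linalg.norm(top)
            assert abs(abs(v @ top) - 1.0) < 1e-10

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(5, 5))
        S = (A + A.T) / 2
        np.testing.assert_allclose(
            leading_eigenvector(S), leading_eigenvector(2 * S), atol=1e-10
        )

    def test_majority_negative_sign_convention(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = rng.normal(size=(7, 7))
            v = leading_eigenvector((A + A.T) / 2)
            assert np.sum(v < 0) >= np.sum(v > 0)


class TestOuterPattern:
    def test_uniform_vector_gives_constant_matrix(self):
        v = np.full(4, -0.5)
        np.testing.assert_allclose(outer_pattern(v), 0.25, atol=1e-15)

    def test_rank_one_trace_one_and_eigenpair(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        P = outer_pattern(v)
        assert abs(np.trace(P) - 1.0) < 1e-12
        vals, vecs = np.linalg.eigh(P)
        assert abs(vals[-1] - 1.0) < 1e-12
        assert abs(abs(vecs[:, -1] @ v) - 1.0) < 1e-12
        assert np.all(np.abs(vals[:-1]) < 1e-12)

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError, match="unit norm"):
            outer_pattern(np.array([1.0, 1.0]))


class TestFCD:
    def test_identical_and_opposed_eigenvectors(self):
        v = np.array([1.0, 0.0, 0.0])
        series = EigenvectorSeries(np.vstack([v, v, -v]))
        f = fcd_matrix(series)
        assert f.fcd[0, 1] == 1.0 and f.fcd[0, 2] == -1.0
        np.testing.assert_allclose(np.diag(f.fcd), 1.0, atol=1e-12)

    def test_orthogonal_eigenvectors(self):
        series = EigenvectorSeries(np.eye(3))
        f = fcd_matrix(series)
        assert f.fcd[0, 1] == 0.0
        assert abs(f.mean_similarity) < 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_entries_bounded_for_random_series(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.normal(size=(10, 5))
        V /= np.linalg.norm(V, axis=1, keepdims=True)
        f = fcd_matrix(EigenvectorSeries(V))
        assert np.all(f.fcd <= 1.0) and np.all(f.fcd >= -1.0)
        np.testing.assert_allclose(f.fcd, f.fcd.T, atol=1e-12)


class TestLeidaCohort:
    def test_synchronised_cohort_single_dominant_state(self):
        # nearly always synchronised, with rare desynchronised volumes that
        # absorb the second (forced) cluster
        n = 6
        sync = np.ones((n, n))
        offsets = np.array([[0.0] * n, [0.0, 2.0, 4.0, 1.0, 3.0, 5.0]])
        seq = np.ones(120, dtype=int)
        seq[[30, 31, 70, 71, 100, 101]] = 2
        subjects = [
            generate_phase_coupled(
                seq, n, 0.05, [sync, sync], tr_seconds=2.072, seed=40 + s,
                amplitude_noise_sd=0.02, phase_offsets=offsets, subject_id=f"s{s}",
            )
            for s in range(3)
        ]
        _, metrics, fcd = leida_cohort_analysis(subjects, k=2, n_restarts=5, seed=0)
        top = metrics[metrics.state == 1]
        assert (top.frequency > 0.9).all()
        assert (fcd.mean_fcd_similarity > 0.8).all()

    def test_planted_coupling_regimes_recovered(self):
        # two regimes: global synchrony vs two anti-phase blocks
        n = 6
        sync = np.ones((n, n))
        offsets = np.array([[0.0] * n, [0.0, 0.0, 0.0, np.pi, np.pi, np.pi]])
        recovered = []
        subjects, truth = [], []
        for s in range(4):
            rng = np.random.default_rng(50 + s)
            seq = np.repeat([1, 2, 1, 2], 40)
            tc = generate_phase_coupled(
                seq, n, 0.05, [sync, sync], tr_seconds=2.072, seed=rng,
                amplitude_noise_sd=0.05, phase_offsets=offsets,
                subject_id=f"s{s}",
            )
            subjects.append(tc)
            truth.append(seq[1:-1])  # drop_edges=1
        model, metrics, _ = leida_cohort_analysis(subjects, k=2, n_restarts=10, seed=1)
        labels = model.labels
        pooled_truth = np.concatenate(truth)
        agree = np.mean(labels == pooled_truth)
        recovered = max(agree, 1 - agree)  # label permutation
        assert recovered >= 0.8

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(5)
        subjects = [
            NetworkTimecourses(f"s{i}", rng.normal(size=(60, 4)), 2.072) for i in range(3)
        ]
        _, metrics, _ = leida_cohort_analysis(subjects, k=3, n_restarts=5, seed=2)
        sums = metrics.groupby("subject_id").frequency.sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_inconsistent_network_count_rejected(self):
        rng = np.random.default_rng(6)
        a = NetworkTimecourses("a", rng.normal(size=(60, 4)), 2.0)
        b = NetworkTimecourses("b", rng.normal(size=(60, 5)), 2.0)
        with pytest.raises(ValueError, match="differing"):
            leida_cohort_analysis([a, b], k=2)


def test_subject_eigenvectors_unit_norm():
    rng = np.random.default_rng(7)
    tc = NetworkTimecourses("s", rng.normal(size=(80, 5)), 2.072)
    series = subject_eigenvectors(tc)
    assert series.V1.shape == (78, 5)
    np.testing.assert_allclose(np.linalg.norm(series.V1, axis=1), 1.0, atol=1e-10)
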